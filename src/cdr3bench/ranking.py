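"""Common container for detector outputs: ordered interaction rankings."""

from __future__ import annotations

from dataclasses import dataclass, field

from ._exceptions import ValidationError
from .seqsim import Cov, cov_label


@dataclass
class InteractionRanking:
    """A detector's ordered candidate interactions with scores.

    ``entries`` is a list of ``(covariate set, score)`` pairs in
    non-increasing score order; ties are broken lexicographically by the
    sorted covariate labels.  ``flavor`` distinguishes pairwise-only lists
    from any-order lists.
    """

    entries: list[tuple[frozenset[Cov], float]]
    flavor: str = "any"
    detector: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        prev = None
        for s, score in self.entries:
            if len(s) < 2:
                raise ValidationError("interaction sets must have size >= 2")
            if s in seen:
                raise ValidationError("duplicate interaction set in ranking")
            seen.add(s)
            if prev is not None and score > prev + 1e-12:
                raise ValidationError("ranking scores must be non-increasing")
            prev = score

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, k: int = 10) -> list[frozenset[Cov]]:
        return [s for s, _ in self.entries[:k]]

    def labels(self, k: int | None = None) -> list[str]:
        ent = self.entries if k is None else self.entries[:k]
        return [":".join(sorted(cov_label(c) for c in s)) for s, _ in ent]

    def to_dataframe(self):
        """Tidy table: one row per candidate set (set, score, order)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "set": self.labels(),
                "score": [score for _, score in self.entries],
                "order": [len(s) for s, _ in self.entries],
            }
        )


def sort_key(cov_set) -> tuple:
    """Deterministic lexicographic key for a covariate set (for tie-breaking)."""
    return tuple(sorted(cov_set))


def build_ranking(
    scores: dict, columns=None, flavor: str = "any", detector: str = "", k: int | None = None
) -> InteractionRanking:
    """Turn a ``{index-or-cov tuple: score}`` dict into a sorted ranking.

    If ``columns`` is given, integer feature indices are mapped to covariate
    identities through it.
    """
    entries = []
    for key, score in scores.items():
        covs = frozenset(columns[i] for i in key) if columns is not None else frozenset(key)
        entries.append((covs, float(score)))
    entries.sort(key=lambda e: (-e[1], sort_key(e[0])))
    if k is not None:
        entries = entries[:k]
    return InteractionRanking(entries, flavor=flavor, detector=detector)
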