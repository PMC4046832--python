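"""Literature-association weights and the literature-support score.

Works from user-supplied term-frequency and shared-concept tables (text
mining and retrieval are outside this package). Two weights per mark
pair are available: a co-occurrence weight from how often the two mark
terms appear together in the corpus, and a shared-concept weight from
the joint significance of concepts both marks associate with. The
literature-support score of a ranked edge list is the sum of weights of
the N most significant model edges (model order, not weight order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .errors import ValidationError

__all__ = [
    "TermFrequencies",
    "SharedConceptTable",
    "cooccurrence_weight",
    "shared_concept_weight",
    "literature_support",
]


def _dice(f_ab: float, f_a: float, f_b: float) -> float:
    return 0.0 if f_a + f_b == 0 else 2.0 * f_ab / (f_a + f_b)


def _geometric(f_ab: float, f_a: float, f_b: float) -> float:
    return 0.0 if f_a * f_b == 0 else f_ab / (f_a * f_b) ** 0.5


_WEIGHT_FORMS: dict[str, Callable[[float, float, float], float]] = {
    "dice": _dice,
    "geometric": _geometric,
}


@dataclass
class TermFrequencies:
    """Corpus frequencies of single terms and unordered term pairs."""

    freq_single: dict[str, float]
    freq_pair: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, f in self.freq_single.items():
            if f < 0:
                raise ValidationError(f"negative frequency for {term!r}")
        for pair, f in self.freq_pair.items():
            if f < 0:
                raise ValidationError(f"negative pair frequency for {set(pair)}")
            singles = [self.freq_single.get(t) for t in pair]
            if any(s is not None and f > s for s in singles):
                raise ValidationError(
                    f"pair frequency {f} for {set(pair)} exceeds a marginal"
                )

    def pair(self, a: str, b: str) -> float:
        return float(self.freq_pair.get(frozenset((a, b)), 0.0))


@dataclass
class SharedConceptTable:
    """Per-pair shared concepts with their two association significances.

    Each entry is (concept, sig_a, sig_b), sorted by joint significance
    (sig_a * sig_b) descending. ``n_top`` is the default number of top
    concepts entering the shared-concept weight.
    """

    concepts: dict[frozenset, list[tuple[str, float, float]]]
    n_top: int = 5

    def __post_init__(self) -> None:
        if self.n_top < 1:
            raise ValidationError("n_top must be >= 1")
        self.concepts = {
            k: sorted(v, key=lambda c: -(c[1] * c[2]))
            for k, v in self.concepts.items()
        }


def cooccurrence_weight(pair: tuple[str, str], tf: TermFrequencies,
                        form: str | Callable = "dice") -> float:
    """Corpus co-occurrence weight of a mark pair, in [0, 1] for Dice.

    Dice form: w = 2 freq(a, b) / (freq(a) + freq(b)); 0/0 is defined
    as 0. Alternative forms are pluggable by name or callable.
    """
    a, b = pair
    for t in (a, b):
        if t not in tf.freq_single:
            raise ValidationError(f"unknown term {t!r}")
    fn = _WEIGHT_FORMS[form] if isinstance(form, str) else form
    return float(fn(tf.pair(a, b), tf.freq_single[a], tf.freq_single[b]))


def shared_concept_weight(pair: tuple[str, str], sc: SharedConceptTable,
                          n_top: int | None = None) -> float:
    """Sum of sig_a * sig_b over the top shared concepts of the pair."""
    n = n_top if n_top is not None else sc.n_top
    if n < 1:
        raise ValidationError("n_top must be >= 1")
    entries = sc.concepts.get(frozenset(pair), [])
    return float(sum(s1 * s2 for _, s1, s2 in entries[:n]))


def literature_support(edge_weights: list[float], n: int) -> float:
    """Sum of the weights of the N most significant model edges.

    ``edge_weights`` must already be in model-significance order; only
    the first min(N, len) entries contribute.
    """
    if n < 1:
        raise ValidationError("N must be >= 1")
    if any(w < 0 for w in edge_weights):
        raise ValidationError("weights must be non-negative")
    return float(sum(edge_weights[:n]))
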