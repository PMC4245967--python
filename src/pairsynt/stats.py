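"""Binomial enrichment statistics.

The enrichment question asked of a gene set (e.g. "are the carriers of this
conserved synteny enriched in pathogens?", "does the dispensable genome
pile up in known mobile-element loci?") is answered with the binomial law:
observing k successes among n trials when each trial succeeds with
probability p.  Both the point probability P(X = k) and the upper tail
P(X ≥ k) are always computed; the *point* probability is the default
reported value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import binom

from .genome_io import ValidationError

POINT = "point"
UPPER_TAIL = "upper_tail"


@dataclass(frozen=True)
class BinomialResult:
    """Outcome of one binomial test; ``mode`` selects the headline p-value."""

    k: int
    n: int
    p: float
    point_prob: float
    upper_tail: float
    mode: str = POINT

    @property
    def pvalue(self) -> float:
        return self.point_prob if self.mode == POINT else self.upper_tail

    def to_dict(self) -> dict:
        return {
            "k": self.k, "n": self.n, "p": self.p, "mode": self.mode,
            "pvalue": self.pvalue, "point_prob": self.point_prob,
            "upper_tail": self.upper_tail,
        }


def binomial_pvalue(k: int, n: int, p: float, mode: str = POINT) -> BinomialResult:
    """P(X = k) and P(X ≥ k) for X ~ Binomial(n, p).

    Probabilities are computed in log space (no underflow for the extreme
    p-values typical of enrichment tests).
    """
    if not (isinstance(k, int) and isinstance(n, int)):
        raise ValidationError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValidationError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"require 0 <= p <= 1, got p={p}")
    if mode not in (POINT, UPPER_TAIL):
        raise ValidationError(f"unknown mode {mode!r}")
    point = float(binom.pmf(k, n, p))
    upper = float(binom.sf(k - 1, n, p)) if k > 0 else 1.0
    return BinomialResult(k, n, p, point, upper, mode)


def locus_overlap_test(gene_set: Iterable[str], loci: Sequence,
                       genome_size_genes: int, mode: str = POINT) -> BinomialResult:
    """Is *gene_set* enriched in the union of the given loci?

    n = |gene_set| trials, k = genes of the set falling in ∪loci, and
    p = |∪loci| / genome_size_genes, i.e. the success probability of a gene
    drawn uniformly from the genome.
    """
    genes = set(gene_set)
    if not genes:
        raise ValidationError("gene_set must be non-empty")
    union = set()
    for locus in loci:
        union |= set(locus)
    if genome_size_genes < len(union) or genome_size_genes < 1:
        raise ValidationError(
            f"genome_size_genes={genome_size_genes} smaller than the loci union"
        )
    k = len(genes & union)
    return binomial_pvalue(k, len(genes), len(union) / genome_size_genes, mode)
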