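"""Analytic probabilities and likelihood ratios for source attribution.

Three layers, all exactly consistent with the simulation modules:

* **Sampling detection** — under binomial cell sampling, the probability that
  none of ``n`` sampled cells comes from a contributor of mixture proportion
  ``p`` is ``(1 - p)**n``.
* **Genotype probabilities** — Balding-Nichols theta-corrected: for allele
  frequency p and substructure coefficient theta, P(AA) = p(theta + (1-theta)p)
  and P(AB) = 2 p q (1 - theta); a profile probability (the random match
  probability, RMP) is the product over loci.
* **Observation (transition) probabilities** — the exact probability of an
  observed single-locus call set given a true genotype under the generative
  drop-out-then-miscall model of :mod:`scstrmix.cell_sim`, obtained by
  enumerating every drop/miscall outcome at the locus.

Likelihood ratios compare a consensus profile A with a reference genotype B.
Under the same-source hypothesis the numerator is the genotype probability of
B times the probability of observing A from B; the denominator is the product
of the genotype frequencies of A (read as a genotype) and B, so with no
drop-out/drop-in and A = B the LR reduces to 1 / RMP(A).  For kinship
hypotheses both the numerator and the denominator marginalize A's latent true
genotype over the IBD-state mixture (k0, k1, k2), with theta-corrected
conditional allele draws continuing the Balding-Nichols recursion past B's
two alleles; the unrelated hypothesis (1, 0, 0) therefore gives LR = 1
identically.  Mutation is not modeled in the kinship transitions.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .cell_sim import DropModel, simulate_diploid_cell
from .consensus import ConsensusProfile, consensus_profile
from .freq_panel import AlleleFrequencyTable
from .genotype_sim import GenotypeProfile, sample_genotype_fst

__all__ = [
    "RelationshipHypothesis",
    "prob_missing_contributor",
    "genotype_probability",
    "profile_probability",
    "observation_probability",
    "observation_distribution",
    "lr_same_source",
    "lr_related",
    "estimate_consensus_error_rates",
]


@dataclass(frozen=True)
class RelationshipHypothesis:
    """A pairwise kinship hypothesis as IBD coefficients (k0, k1, k2)."""

    kind: str
    ibd_coefficients: tuple[float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.ibd_coefficients) - 1.0) > 1e-9:
            raise ValueError("IBD coefficients must sum to 1")

    @classmethod
    def from_kind(cls, kind: str) -> "RelationshipHypothesis":
        table = {
            "unrelated": (1.0, 0.0, 0.0),
            "parent-child": (0.0, 1.0, 0.0),
            "full-siblings": (0.25, 0.5, 0.25),
        }
        if kind not in table:
            raise ValueError(f"unknown relationship kind {kind!r}")
        return cls(kind=kind, ibd_coefficients=table[kind])


def prob_missing_contributor(p: float, n: int) -> float:
    """Probability that none of ``n`` sampled cells comes from a ``p``-proportion contributor."""
    if not (0.0 < p < 1.0):
        raise ValueError("mixture proportion p must be in (0, 1)")
    if n < 0:
        raise ValueError("n must be >= 0")
    return (1.0 - p) ** n


def _conditional_allele_probs(
    table: AlleleFrequencyTable, locus: str, prev: tuple[float, ...], fst: float
) -> np.ndarray:
    """Theta-corrected conditional allele distribution after ``prev`` draws."""
    alleles = table.alleles(locus)
    p = table.freqs(locus)
    n = len(prev)
    if n == 0 or fst == 0.0:
        return p
    counts = np.array([prev.count(a) for a in alleles], dtype=float)
    probs = (counts * fst + (1.0 - fst) * p) / (1.0 + (n - 1) * fst)
    return probs / probs.sum()


def genotype_probability(
    genotype: tuple[float, float],
    locus: str,
    table: AlleleFrequencyTable,
    fst: float = 0.0,
) -> float:
    """Balding-Nichols probability of a single-locus genotype."""
    a, b = genotype
    alleles = table.alleles(locus)
    pa = _conditional_allele_probs(table, locus, (), fst)[alleles.index(a)]
    pb_given_a = _conditional_allele_probs(table, locus, (a,), fst)[alleles.index(b)]
    prob = pa * pb_given_a
    return float(prob if a == b else 2.0 * prob)


def profile_probability(
    profile: GenotypeProfile, table: AlleleFrequencyTable, fst: float = 0.0
) -> float:
    """Random match probability of a full profile (product over loci)."""
    rmp = 1.0
    for locus in table.loci:
        rmp *= genotype_probability(profile.pair(locus), locus, table, fst)
    return rmp


def _miscall_dist(allele: float, alleles: tuple[float, ...], e: float) -> dict[float, float]:
    out = {a: 0.0 for a in alleles}
    out[allele] += 1.0 - e
    if e > 0.0:
        share = e / (len(alleles) - 1)
        for a in alleles:
            if a != allele:
                out[a] += share
    return {a: p for a, p in out.items() if p > 0.0}


def observation_distribution(
    true_genotype: tuple[float, float],
    model: DropModel,
    alleles: tuple[float, ...],
) -> dict[tuple[float, ...], float]:
    """Exact distribution of the observed diploid call multiset at one locus.

    Enumerates every drop-out pattern and miscall target of the generative
    model (drop-out first, miscalls on survivors only); the returned
    probabilities sum to 1.
    """
    a, b = true_genotype
    dist: dict[tuple[float, ...], float] = defaultdict(float)
    if a == b:
        dist[()] += model.D2
        base = 1.0 - model.D2
        if base > 0.0:
            mc = _miscall_dist(a, alleles, model.e)
            for (c1, p1), (c2, p2) in itertools.product(mc.items(), repeat=2):
                dist[tuple(sorted((c1, c2)))] += base * p1 * p2
    else:
        for drop_a, drop_b in itertools.product((False, True), repeat=2):
            pattern = (model.D if drop_a else 1.0 - model.D) * (
                model.D if drop_b else 1.0 - model.D
            )
            if pattern == 0.0:
                continue
            survivors = [x for x, dropped in ((a, drop_a), (b, drop_b)) if not dropped]
            if not survivors:
                dist[()] += pattern
            elif len(survivors) == 1:
                for c, p in _miscall_dist(survivors[0], alleles, model.e).items():
                    dist[(c,)] += pattern * p
            else:
                mc1 = _miscall_dist(survivors[0], alleles, model.e)
                mc2 = _miscall_dist(survivors[1], alleles, model.e)
                for (c1, p1), (c2, p2) in itertools.product(mc1.items(), mc2.items()):
                    dist[tuple(sorted((c1, c2)))] += pattern * p1 * p2
    return dict(dist)


def observation_probability(
    observed: tuple[float, ...],
    true_genotype: tuple[float, float],
    model: DropModel,
    alleles: tuple[float, ...],
) -> float:
    """Probability of one observed call multiset given the true genotype."""
    dist = observation_distribution(true_genotype, model, alleles)
    return dist.get(tuple(sorted(observed)), 0.0)


def _conditional_genotype_dist(
    b_pair: tuple[float, float],
    hypothesis: RelationshipHypothesis,
    locus: str,
    table: AlleleFrequencyTable,
    fst: float,
) -> dict[tuple[float, float], float]:
    """P(true genotype of A | genotype of B, IBD coefficients, theta)."""
    k0, k1, k2 = hypothesis.ibd_coefficients
    alleles = table.alleles(locus)
    dist: dict[tuple[float, float], float] = defaultdict(float)
    if k2 > 0.0:
        dist[b_pair] += k2
    if k1 > 0.0:
        cond = _conditional_allele_probs(table, locus, b_pair, fst)
        for t in b_pair:
            for u, pu in zip(alleles, cond):
                if pu > 0.0:
                    pair = (min(t, u), max(t, u))
                    dist[pair] += k1 * 0.5 * pu
    if k0 > 0.0:
        cond1 = _conditional_allele_probs(table, locus, b_pair, fst)
        for u1, p1 in zip(alleles, cond1):
            if p1 == 0.0:
                continue
            cond2 = _conditional_allele_probs(table, locus, b_pair + (u1,), fst)
            for u2, p2 in zip(alleles, cond2):
                if p2 > 0.0:
                    pair = (min(u1, u2), max(u1, u2))
                    dist[pair] += k0 * p1 * p2
    return dict(dist)


def _consensus_locus_calls(a: ConsensusProfile, locus: str) -> tuple[float, ...]:
    return tuple(x for x in a.calls[locus] if x is not None)


def lr_same_source(
    a: ConsensusProfile,
    b: GenotypeProfile,
    model: DropModel,
    table: AlleleFrequencyTable,
    fst: float = 0.0,
    return_per_locus: bool = False,
):
    """Likelihood ratio for "A and B share a source" vs "A and B are unrelated".

    Per locus the numerator is P(genotype B) * P(observed A | B) under the
    drop-out/drop-in ``model`` (typically consensus-level effective rates),
    and the denominator is P(A read as a genotype) * P(genotype B).  Loci
    where A is fully missing contribute a factor of 1; a half-missing locus is
    not representable as a genotype and is also skipped, with a warning.
    """
    if a.loci != b.loci:
        raise ValueError("profiles are typed at different loci")
    lr = 1.0
    per_locus: dict[str, float] = {}
    for locus in b.loci:
        obs = _consensus_locus_calls(a, locus)
        if len(obs) == 0:
            per_locus[locus] = 1.0
            continue
        if len(obs) == 1:
            warnings.warn(
                f"locus {locus!r}: consensus is half-missing and not representable "
                "as a genotype; treated as uninformative (factor 1)",
                UserWarning,
                stacklevel=2,
            )
            per_locus[locus] = 1.0
            continue
        numer = observation_probability(obs, b.pair(locus), model, table.alleles(locus))
        denom = genotype_probability((obs[0], obs[1]), locus, table, fst)
        factor = numer / denom
        per_locus[locus] = factor
        lr *= factor
    return (lr, per_locus) if return_per_locus else lr


def lr_related(
    a: ConsensusProfile,
    b: GenotypeProfile,
    hypothesis: RelationshipHypothesis,
    model: DropModel,
    table: AlleleFrequencyTable,
    fst: float = 0.0,
    return_per_locus: bool = False,
):
    """Likelihood ratio for "A is a ``hypothesis`` relative of B" vs "unrelated".

    Both hypotheses marginalize the latent true genotype G of A: the numerator
    sums P(G | B, k0, k1, k2, theta) * P(observed A | G) and the denominator
    does the same with unrelated coefficients (1, 0, 0), so the unrelated
    hypothesis yields LR = 1 for any profiles.  Mutation is ignored in the
    kinship transition.
    """
    if a.loci != b.loci:
        raise ValueError("profiles are typed at different loci")
    unrelated = RelationshipHypothesis.from_kind("unrelated")
    lr = 1.0
    per_locus: dict[str, float] = {}
    for locus in b.loci:
        obs = _consensus_locus_calls(a, locus)
        if len(obs) != 2:
            if len(obs) == 1:
                warnings.warn(
                    f"locus {locus!r}: consensus is half-missing; "
                    "treated as uninformative (factor 1)",
                    UserWarning,
                    stacklevel=2,
                )
            per_locus[locus] = 1.0
            continue
        alleles = table.alleles(locus)
        obs_sorted = tuple(sorted(obs))

        def hypothesis_prob(hyp: RelationshipHypothesis) -> float:
            total = 0.0
            for g, pg in _conditional_genotype_dist(
                b.pair(locus), hyp, locus, table, fst
            ).items():
                total += pg * observation_probability(obs_sorted, g, model, alleles)
            return total

        numer = hypothesis_prob(hypothesis)
        denom = hypothesis_prob(unrelated)
        factor = numer / denom if denom > 0 else float("inf") if numer > 0 else 1.0
        per_locus[locus] = factor
        lr *= factor
    return (lr, per_locus) if return_per_locus else lr


def estimate_consensus_error_rates(
    table: AlleleFrequencyTable,
    model: DropModel,
    cluster_size: int,
    n_sim: int = 200,
    fst: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DropModel:
    """Empirical consensus-level effective drop-out / drop-in rates.

    A consensus over a cluster of cells has much lower missing-call and
    miscall rates than a single cell; likelihood ratios on consensus profiles
    should use these effective rates.  Simulates ``n_sim`` clusters of
    ``cluster_size`` diploid cells and measures, against truth: the per-allele
    missing rate at heterozygous loci (effective D), the whole-locus missing
    rate at homozygous loci (effective D2), and the per-called-slot wrong-call
    rate (effective e).
    """
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    rng = rng or np.random.default_rng()
    het_slots = het_missing = 0
    hom_loci = hom_dropped = 0
    called = wrong = 0
    for _ in range(n_sim):
        truth = sample_genotype_fst(table, fst, rng)
        cells = [
            simulate_diploid_cell(truth, table, model, rng) for _ in range(cluster_size)
        ]
        cons = consensus_profile(cells)
        for locus in table.loci:
            t1, t2 = truth.pair(locus)
            c1, c2 = cons.calls[locus]
            if t1 == t2:
                hom_loci += 1
                if c1 is None and c2 is None:
                    hom_dropped += 1
            else:
                het_slots += 2
                het_missing += int(c1 is None) + int(c2 is None)
            for c, t in ((c1, t1), (c2, t2)):
                if c is not None:
                    called += 1
                    wrong += int(c != t)
    d_eff = het_missing / het_slots if het_slots else 0.0
    d2_eff = hom_dropped / hom_loci if hom_loci else 0.0
    e_eff = wrong / called if called else 0.0
    return DropModel(D=d_eff, e=e_eff, D2=d2_eff)
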