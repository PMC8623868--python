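"""Simulation of true contributor genotypes.

Contributors are diploid individuals typed at the panel loci.  Alleles are
drawn from the panel frequencies with a population-substructure (theta / Fst)
correction: within one individual, the i-th allele draw at a locus is allele A
with probability

    (x * theta + (1 - theta) * p_A) / (1 + (n - 1) * theta)

where ``x`` is the number of copies of A among the ``n`` alleles already drawn
at that locus (the Balding-Nichols / Polya-urn conditional).  With theta = 0
this reduces to Hardy-Weinberg sampling.  Loci are independent and each
individual's draws are conditioned only on that individual's own previous
draws at the locus.

Relatives are built by Mendelian transmission: each parent passes one of its
two alleles with probability 1/2, subject to a two-phase microsatellite
mutation model (a rate per transmission; single-step +/-1 changes with
probability ``p_single_step``, otherwise a geometric multi-step change).
Mutated designations falling outside the panel allele list are clamped to the
nearest panel allele so that every simulated allele keeps a defined frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .freq_panel import AlleleFrequencyTable, PanelError, format_allele

__all__ = [
    "GenotypeProfile",
    "MutationModel",
    "RelationshipSpec",
    "sample_genotype_fst",
    "transmit_allele",
    "simulate_contributors",
    "write_genotypes_csv",
]


@dataclass(frozen=True)
class GenotypeProfile:
    """A contributor's true diploid genotype: one ascending allele pair per locus."""

    contributor_id: str
    genotypes: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for locus, pair in self.genotypes.items():
            if len(pair) != 2:
                raise ValueError(f"locus {locus!r}: genotype must be an allele pair")
            if pair[0] > pair[1]:
                raise ValueError(
                    f"locus {locus!r}: pair {pair} not stored in ascending order"
                )

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.genotypes)

    def pair(self, locus: str) -> tuple[float, float]:
        return self.genotypes[locus]


@dataclass(frozen=True)
class MutationModel:
    """Two-phase microsatellite mutation model for parent-child transmissions.

    ``rate_per_locus`` is the mutation probability per transmission;
    ``p_single_step`` the probability that a mutation is a +/-1 repeat change;
    multi-step changes move by k >= 2 repeats with k - 1 geometric with
    parameter ``geometric_p``.  Directions are equiprobable.
    """

    rate_per_locus: float = 1.5e-3
    p_single_step: float = 0.9
    geometric_p: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate_per_locus <= 1.0):
            raise ValueError("rate_per_locus must be in [0, 1]")
        if not (0.0 <= self.p_single_step <= 1.0):
            raise ValueError("p_single_step must be in [0, 1]")
        if not (0.0 < self.geometric_p <= 1.0):
            raise ValueError("geometric_p must be in (0, 1]")


_VALID_KINDS = ("unrelated-set", "parent-child", "full-siblings", "trio")


@dataclass(frozen=True)
class RelationshipSpec:
    """Which pedigree structure the contributors of a mixture form."""

    kind: str
    n_contributors: int

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unsupported relationship kind {self.kind!r}")
        if self.kind == "trio" and self.n_contributors != 3:
            raise ValueError("a trio has exactly 3 contributors (father, mother, child)")
        if self.kind in ("parent-child", "full-siblings") and self.n_contributors != 2:
            raise ValueError(f"{self.kind} implies exactly 2 contributors")
        if self.n_contributors < 1:
            raise ValueError("n_contributors must be >= 1")


def _draw_allele(
    table: AlleleFrequencyTable,
    locus: str,
    prev: list[float],
    fst: float,
    rng: np.random.Generator,
) -> float:
    """One theta-corrected allele draw, conditional on ``prev`` earlier draws."""
    alleles = table.alleles(locus)
    p = table.freqs(locus)
    n = len(prev)
    if n == 0 or fst == 0.0:
        probs = p
    else:
        counts = np.array([prev.count(a) for a in alleles], dtype=float)
        probs = (counts * fst + (1.0 - fst) * p) / (1.0 + (n - 1) * fst)
        probs = probs / probs.sum()
    u = rng.random()
    idx = int(np.searchsorted(np.cumsum(probs), u))
    idx = min(idx, len(alleles) - 1)
    return alleles[idx]


def sample_genotype_fst(
    table: AlleleFrequencyTable,
    fst: float,
    rng: np.random.Generator,
    contributor_id: str = "C1",
) -> GenotypeProfile:
    """Draw one individual's genotype under the Balding-Nichols model."""
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1)")
    genotypes: dict[str, tuple[float, float]] = {}
    for locus in table.loci:
        a1 = _draw_allele(table, locus, [], fst, rng)
        a2 = _draw_allele(table, locus, [a1], fst, rng)
        genotypes[locus] = (min(a1, a2), max(a1, a2))
    return GenotypeProfile(contributor_id=contributor_id, genotypes=genotypes)


def transmit_allele(
    parent: GenotypeProfile,
    locus: str,
    table: AlleleFrequencyTable,
    model: MutationModel,
    rng: np.random.Generator,
) -> float:
    """Transmit one parental allele at ``locus``, applying the mutation model."""
    if locus not in parent.genotypes:
        raise PanelError(f"unknown locus {locus!r} for contributor {parent.contributor_id}")
    pair = parent.pair(locus)
    allele = pair[0] if rng.random() < 0.5 else pair[1]
    if rng.random() < model.rate_per_locus:
        if rng.random() < model.p_single_step:
            step = 1
        else:
            step = 1 + int(rng.geometric(model.geometric_p))  # k >= 2
        direction = 1.0 if rng.random() < 0.5 else -1.0
        mutated = allele + direction * step
        panel_alleles = np.asarray(table.alleles(locus))
        # clamp to the nearest representable allele (ties -> smaller)
        allele = float(panel_alleles[np.argmin(np.abs(panel_alleles - mutated))])
    return allele


def _child(
    father: GenotypeProfile,
    mother: GenotypeProfile,
    table: AlleleFrequencyTable,
    model: MutationModel,
    rng: np.random.Generator,
    contributor_id: str,
) -> GenotypeProfile:
    genotypes = {}
    for locus in table.loci:
        a = transmit_allele(father, locus, table, model, rng)
        b = transmit_allele(mother, locus, table, model, rng)
        genotypes[locus] = (min(a, b), max(a, b))
    return GenotypeProfile(contributor_id=contributor_id, genotypes=genotypes)


def simulate_contributors(
    spec: RelationshipSpec,
    table: AlleleFrequencyTable,
    fst: float = 0.01,
    model: MutationModel | None = None,
    rng: np.random.Generator | None = None,
) -> list[GenotypeProfile]:
    """Simulate the true genotypes of every contributor of a mixture.

    * ``unrelated-set``: n independent population draws.
    * ``parent-child``: the child inherits one transmitted allele per locus;
      the other allele is a theta-conditional population draw given the
      child's own transmitted allele.
    * ``full-siblings``: two unobserved parents, two children by independent
      transmissions.
    * ``trio``: father, mother and one child.
    """
    model = model or MutationModel()
    rng = rng or np.random.default_rng()
    if spec.kind == "unrelated-set":
        return [
            sample_genotype_fst(table, fst, rng, contributor_id=f"C{i + 1}")
            for i in range(spec.n_contributors)
        ]
    if spec.kind == "parent-child":
        parent = sample_genotype_fst(table, fst, rng, contributor_id="parent")
        genotypes = {}
        for locus in table.loci:
            t = transmit_allele(parent, locus, table, model, rng)
            other = _draw_allele(table, locus, [t], fst, rng)
            genotypes[locus] = (min(t, other), max(t, other))
        child = GenotypeProfile(contributor_id="child", genotypes=genotypes)
        return [parent, child]
    if spec.kind == "full-siblings":
        father = sample_genotype_fst(table, fst, rng, contributor_id="father")
        mother = sample_genotype_fst(table, fst, rng, contributor_id="mother")
        return [
            _child(father, mother, table, model, rng, "sib1"),
            _child(father, mother, table, model, rng, "sib2"),
        ]
    if spec.kind == "trio":
        father = sample_genotype_fst(table, fst, rng, contributor_id="father")
        mother = sample_genotype_fst(table, fst, rng, contributor_id="mother")
        child = _child(father, mother, table, model, rng, "child")
        return [father, mother, child]
    raise ValueError(f"unsupported relationship kind {spec.kind!r}")


def write_genotypes_csv(profiles: list[GenotypeProfile], path) -> None:
    """Serialize genotype profiles as ``contributor_id,locus,allele1,allele2``."""
    with open(path, "w") as fh:
        fh.write("contributor_id,locus,allele1,allele2\n")
        for prof in profiles:
            for locus, (a1, a2) in prof.genotypes.items():
                fh.write(
                    f"{prof.contributor_id},{locus},{format_allele(a1)},{format_allele(a2)}\n"
                )
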