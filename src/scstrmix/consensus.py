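"""Per-contributor consensus profiles from clustered cells.

Each allele slot of the consensus is the modal observed allele at that slot
among the cells of a cluster; missing calls cast no vote and ties break
toward the smaller allele designation.  For haploid clusters the per-locus
vote is expanded to a diploid profile: the two most frequent distinct alleles
fill the two slots ascending, and a single observed allele is duplicated
(so the consensus of one haploid cell is homozygous at every called locus).

Consensus accuracy against a truth genotype is the fraction of the 2L truth
allele slots (truth stored ascending per locus) recovered exactly; a missing
consensus slot counts as incorrect.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cell_sim import CellProfile
from .genotype_sim import GenotypeProfile
from .similarity import ibs_count

__all__ = [
    "ConsensusProfile",
    "consensus_profile",
    "consensus_accuracy",
    "match_clusters_to_truth",
    "write_consensus_csv",
]


@dataclass(frozen=True)
class ConsensusProfile:
    """Majority-vote profile of one cluster, two slots per locus.

    ``calls`` maps each locus to (slot1, slot2) where a slot is an allele or
    ``None``; ``support`` carries the winner's vote count per slot.
    """

    calls: dict[str, tuple[float | None, float | None]]
    support: dict[str, tuple[int, int]]
    cluster_size: int

    def __post_init__(self) -> None:
        for locus, sup in self.support.items():
            if any(s > self.cluster_size for s in sup):
                raise ValueError(f"locus {locus!r}: support exceeds cluster size")

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.calls)


def _modal(votes: list[float]) -> tuple[float | None, int]:
    if not votes:
        return None, 0
    counts = Counter(votes)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))  # ties -> smaller allele
    return best[0], best[1]


def consensus_profile(cells: list[CellProfile]) -> ConsensusProfile:
    """Build the attribute-wise majority consensus of a non-empty cluster."""
    if not cells:
        raise ValueError("cannot build a consensus from an empty cluster")
    ploidies = {c.ploidy for c in cells}
    if len(ploidies) > 1:
        raise ValueError("cluster mixes diploid and haploid cells")
    ploidy = ploidies.pop()
    loci = cells[0].loci
    calls: dict[str, tuple[float | None, float | None]] = {}
    support: dict[str, tuple[int, int]] = {}
    for locus in loci:
        if ploidy == "diploid":
            slot1 = [c.calls[locus][0] for c in cells if len(c.calls[locus]) >= 1]
            slot2 = [c.calls[locus][1] for c in cells if len(c.calls[locus]) == 2]
            (a1, s1), (a2, s2) = _modal(slot1), _modal(slot2)
            calls[locus] = (a1, a2)
            support[locus] = (s1, s2)
        else:
            votes = [c.calls[locus][0] for c in cells if c.calls[locus]]
            counts = Counter(votes)
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
            if not ranked:
                calls[locus] = (None, None)
                support[locus] = (0, 0)
            elif len(ranked) == 1:
                allele, n = ranked[0]
                calls[locus] = (allele, allele)
                support[locus] = (n, n)
            else:
                (x, nx), (y, ny) = ranked
                if x > y:
                    (x, nx), (y, ny) = (y, ny), (x, nx)
                calls[locus] = (x, y)
                support[locus] = (nx, ny)
    return ConsensusProfile(calls=calls, support=support, cluster_size=len(cells))


def consensus_accuracy(consensus: ConsensusProfile, truth: GenotypeProfile) -> float:
    """Fraction of the 2L truth allele slots recovered by the consensus."""
    if consensus.loci != truth.loci:
        raise ValueError("consensus and truth are typed at different loci")
    correct = 0
    total = 0
    for locus in truth.loci:
        t1, t2 = truth.pair(locus)
        c1, c2 = consensus.calls[locus]
        correct += int(c1 == t1) + int(c2 == t2)
        total += 2
    return correct / total


def match_clusters_to_truth(
    consensus_list: list[ConsensusProfile],
    truths: list[GenotypeProfile],
) -> list[int]:
    """One-to-one matching of consensus profiles to true contributors.

    Maximizes total IBS between matched pairs (optimal bipartite assignment);
    scoring is only meaningful when the estimated NOC equals the true NOC, so
    the list lengths must agree.  Returns ``mapping`` with ``mapping[i]`` the
    truth index matched to consensus ``i``.
    """
    if len(consensus_list) != len(truths):
        raise ValueError("consensus and truth lists must have equal length")
    n = len(truths)
    scores = np.zeros((n, n))
    for i, cons in enumerate(consensus_list):
        for j, truth in enumerate(truths):
            scores[i, j] = ibs_count(cons, truth)
    rows, cols = linear_sum_assignment(-scores)
    mapping = [0] * n
    for i, j in zip(rows, cols):
        mapping[i] = int(j)
    return mapping


def write_consensus_csv(profiles: list[ConsensusProfile], path) -> None:
    """Write consensus profiles as CSV with per-slot support counts."""
    from .freq_panel import format_allele

    with open(path, "w") as fh:
        fh.write("cluster,locus,allele1,allele2,support1,support2,cluster_size\n")
        for idx, prof in enumerate(profiles):
            for locus in prof.loci:
                a1, a2 = prof.calls[locus]
                s1, s2 = prof.support[locus]
                fh.write(
                    f"{idx},{locus},"
                    f"{format_allele(a1) if a1 is not None else ''},"
                    f"{format_allele(a2) if a2 is not None else ''},"
                    f"{s1},{s2},{prof.cluster_size}\n"
                )
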