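"""Profile similarity: IBS counting, mismatch distance, MDS coordinates.

Identity-by-state (IBS) between two profiles is counted per locus as the size
of the multiset intersection of the called allele sets (0-2 matches per
locus), summed over loci; missing calls simply contribute no matches.  Over a
21-locus diploid panel the maximum IBS is therefore 42.

The clustering-oriented ``mismatch_distance`` instead works slot-wise on the
packed attribute representation (a slot mismatches when exactly one value is
missing or both are called but unequal; slots missing in both profiles are
excluded), normalized by the number of compared slots.  Classical (Torgerson)
multidimensional scaling of the mismatch-distance matrix provides the 3D
coordinates used to inspect a mixture visually.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np

from .cell_sim import CellProfile, MixtureDataset
from .genotype_sim import GenotypeProfile

__all__ = [
    "ibs_count",
    "mismatch_distance",
    "mds_embed",
    "threshold_error_rate",
    "write_coordinates_csv",
]


def _locus_calls(profile, locus: str) -> tuple[float, ...]:
    """Called alleles of any profile type (genotype / cell / consensus) at a locus."""
    if isinstance(profile, GenotypeProfile):
        return profile.pair(locus)
    if isinstance(profile, CellProfile):
        return profile.calls.get(locus, ())
    # consensus-like: .calls maps locus -> (a1|None, a2|None)
    if hasattr(profile, "calls"):
        return tuple(a for a in profile.calls.get(locus, (None, None)) if a is not None)
    raise TypeError(f"unsupported profile type {type(profile).__name__}")


def _loci_of(profile) -> tuple[str, ...]:
    if isinstance(profile, GenotypeProfile):
        return profile.loci
    return tuple(profile.calls)


def ibs_count(a, b) -> int:
    """Number of identity-by-state allele matches between two profiles.

    Accepts any mix of genotype, diploid cell, and consensus profiles over the
    same panel.  Per locus the contribution is the multiset-intersection size
    of the two called allele sets; alleles missing in either profile do not
    contribute.
    """
    loci_a, loci_b = _loci_of(a), _loci_of(b)
    if loci_a != loci_b:
        raise ValueError("profiles are typed at different loci")
    total = 0
    for locus in loci_a:
        ca = Counter(_locus_calls(a, locus))
        cb = Counter(_locus_calls(b, locus))
        total += sum((ca & cb).values())
    return total


def _slot_vector(cell: CellProfile) -> list[float | None]:
    per_locus = 2 if cell.ploidy == "diploid" else 1
    slots: list[float | None] = []
    for locus in cell.calls:
        obs = cell.calls[locus]
        slots.extend(list(obs) + [None] * (per_locus - len(obs)))
    return slots


def mismatch_distance(a: CellProfile, b: CellProfile) -> float:
    """Fraction of compared allele slots that mismatch between two cells.

    A slot mismatches when exactly one profile is missing there or both are
    called with unequal alleles; slots missing in both are excluded from the
    numerator and the denominator.  Returns 0 when no slots are comparable.
    """
    if a.ploidy != b.ploidy:
        raise ValueError("cells have different ploidy")
    if tuple(a.calls) != tuple(b.calls):
        raise ValueError("cells are typed at different loci")
    va, vb = _slot_vector(a), _slot_vector(b)
    compared = mismatched = 0
    for x, y in zip(va, vb):
        if x is None and y is None:
            continue
        compared += 1
        if x is None or y is None or x != y:
            mismatched += 1
    return mismatched / compared if compared else 0.0


def mds_embed(dataset: MixtureDataset, dims: int = 3) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of every cell, from mismatch distances.

    Double-centers the squared distance matrix and projects on the top ``dims``
    eigenvectors scaled by root-eigenvalues; axes with non-positive eigenvalues
    come out as zero columns.  The sign of each axis is fixed so that its
    largest-magnitude loading is positive, making the output deterministic.
    """
    n = dataset.n_cells
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} cells for a {dims}-D embedding")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = mismatch_distance(dataset.cells[i], dataset.cells[j])
    d2 = dist ** 2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:dims]
    coords = np.zeros((n, dims))
    # axes whose eigenvalue is numerically indistinguishable from zero carry
    # no structure; zero them instead of emitting rounding noise
    floor = n * np.finfo(float).eps * max(eigvals.max(), 0.0)
    for axis, idx in enumerate(order):
        lam = eigvals[idx]
        if lam > floor:
            column = eigvecs[:, idx] * np.sqrt(lam)
            if column[np.argmax(np.abs(column))] < 0:
                column = -column
            coords[:, axis] = column
    return coords


def threshold_error_rate(
    same_source_ibs, different_source_ibs, threshold: int
) -> float:
    """Average of false-positive and false-negative rates for an IBS threshold.

    The classification rule is "same source iff IBS > threshold": a
    different-source pair above the threshold is a false positive, a
    same-source pair at or below it a false negative.
    """
    same = np.asarray(same_source_ibs)
    diff = np.asarray(different_source_ibs)
    if same.size == 0 or diff.size == 0:
        raise ValueError("both IBS samples must be non-empty")
    fpr = float(np.mean(diff > threshold))
    fnr = float(np.mean(same <= threshold))
    return 0.5 * (fpr + fnr)


def write_coordinates_csv(
    dataset: MixtureDataset,
    coords: np.ndarray,
    path,
    assignment=None,
) -> None:
    """Write per-cell MDS coordinates as ``cell_id,x,y,z,cluster,truth_label``."""
    axes = coords.shape[1]
    header = ["cell_id"] + ["xyz"[i] if i < 3 else f"dim{i + 1}" for i in range(axes)]
    header += ["cluster", "truth_label"]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for i, cell in enumerate(dataset.cells):
            cluster = "" if assignment is None else str(int(assignment[i]))
            truth = cell.truth_contributor or ""
            vals = ",".join(f"{coords[i, j]:.6g}" for j in range(axes))
            fh.write(f"{cell.cell_id},{vals},{cluster},{truth}\n")
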