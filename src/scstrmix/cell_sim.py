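"""Observed single-cell STR profiles under allele drop-out / drop-in.

A single cell's profile is its contributor's genotype degraded by two noise
processes:

* **ADO (drop-out)** — at a heterozygous locus each of the two alleles drops
  independently with probability ``D``; a homozygous locus drops as a whole
  with probability ``D2`` (default ``D2 = D^2 / 2``).  Haploid cells carry one
  randomly inherited allele per locus, which drops with probability ``D``.
* **ADI (drop-in / miscall)** — every surviving called allele is independently
  replaced, with probability ``e``, by a uniformly chosen *different* allele
  of that locus.  Drop-out is decided first; miscalls apply to survivors only,
  so a heterozygous drop-in always coincides with the loss of the true allele.

Observed calls at a locus are stored sorted ascending and left-packed: when
one allele of a heterozygote drops, the survivor occupies the first slot and
the second slot is missing.  A called homozygote fills both slots with the
same allele, keeping the attribute geometry at exactly 2L slots for diploid
cells (L for haploid).

Datasets round-trip through a minimal WEKA-style ARFF dialect (one numeric
attribute per allele slot, ``?`` for missing, ``%`` comments) and through a
long-format CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .freq_panel import AlleleFrequencyTable, PanelError, format_allele
from .genotype_sim import GenotypeProfile

__all__ = [
    "DropModel",
    "CellProfile",
    "MixtureDataset",
    "simulate_diploid_cell",
    "simulate_haploid_cell",
    "assemble_mixture",
    "filter_cells",
    "write_arff",
    "read_arff",
    "write_profiles_csv",
    "read_profiles_csv",
]


@dataclass(frozen=True)
class DropModel:
    """Per-cell genotyping error rates.

    ``D``: per-allele drop-out probability at a heterozygous locus.
    ``D2``: whole-locus drop-out probability at a homozygous locus
    (``None`` selects the default ``D**2 / 2``).
    ``e``: per-called-allele miscall (drop-in) probability.
    """

    D: float = 0.2
    e: float = 0.01
    D2: float | None = None

    def __post_init__(self) -> None:
        if self.D2 is None:
            object.__setattr__(self, "D2", 0.5 * self.D * self.D)
        for name in ("D", "D2", "e"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CellProfile:
    """One observed single-cell profile.

    ``calls`` maps each locus to the tuple of observed alleles, sorted
    ascending: 0-2 entries for a diploid cell, 0-1 for a haploid cell.
    """

    cell_id: str
    ploidy: str
    calls: dict[str, tuple[float, ...]]
    truth_contributor: str | None = None

    def __post_init__(self) -> None:
        if self.ploidy not in ("diploid", "haploid"):
            raise ValueError(f"ploidy must be 'diploid' or 'haploid', got {self.ploidy!r}")
        limit = 2 if self.ploidy == "diploid" else 1
        for locus, obs in self.calls.items():
            if len(obs) > limit:
                raise ValueError(f"locus {locus!r}: more than {limit} calls for {self.ploidy}")
            if any(obs[i] > obs[i + 1] for i in range(len(obs) - 1)):
                raise ValueError(f"locus {locus!r}: calls {obs} not sorted ascending")

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.calls)

    def n_called_slots(self) -> int:
        return sum(len(v) for v in self.calls.values())

    def call_fraction(self) -> float:
        per_locus = 2 if self.ploidy == "diploid" else 1
        return self.n_called_slots() / (per_locus * len(self.calls))


@dataclass(frozen=True)
class MixtureDataset:
    """A pooled set of single-cell profiles, with optional hidden truth."""

    cells: tuple[CellProfile, ...]
    panel: AlleleFrequencyTable
    truth: tuple[GenotypeProfile, ...] | None = None

    def __post_init__(self) -> None:
        ploidies = {c.ploidy for c in self.cells}
        if len(ploidies) > 1:
            raise ValueError("all cells of a dataset must share ploidy")
        if self.truth is not None:
            known = {t.contributor_id for t in self.truth}
            for cell in self.cells:
                if cell.truth_contributor is not None and cell.truth_contributor not in known:
                    raise ValueError(
                        f"cell {cell.cell_id}: truth label {cell.truth_contributor!r} "
                        "does not reference a known contributor"
                    )

    @property
    def ploidy(self) -> str:
        return self.cells[0].ploidy if self.cells else "diploid"

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _miscall(allele: float, locus: str, table: AlleleFrequencyTable,
             e: float, rng: np.random.Generator) -> float:
    if e > 0.0 and rng.random() < e:
        others = [a for a in table.alleles(locus) if a != allele]
        return others[int(rng.integers(len(others)))]
    return allele


def simulate_diploid_cell(
    genotype: GenotypeProfile,
    table: AlleleFrequencyTable,
    model: DropModel,
    rng: np.random.Generator,
    cell_id: str = "cell",
) -> CellProfile:
    """Simulate one diploid cell's observed profile from its true genotype."""
    calls: dict[str, tuple[float, ...]] = {}
    for locus in table.loci:
        a, b = genotype.pair(locus)
        if a == b:
            survivors = [] if rng.random() < model.D2 else [a, a]
        else:
            survivors = [x for x in (a, b) if rng.random() >= model.D]
        observed = sorted(_miscall(x, locus, table, model.e, rng) for x in survivors)
        calls[locus] = tuple(observed)
    return CellProfile(cell_id=cell_id, ploidy="diploid", calls=calls,
                       truth_contributor=genotype.contributor_id)


def simulate_haploid_cell(
    genotype: GenotypeProfile,
    table: AlleleFrequencyTable,
    model: DropModel,
    rng: np.random.Generator,
    cell_id: str = "cell",
) -> CellProfile:
    """Simulate one haploid cell: one inherited allele per locus, then ADO/ADI."""
    calls: dict[str, tuple[float, ...]] = {}
    for locus in table.loci:
        pair = genotype.pair(locus)
        allele = pair[0] if rng.random() < 0.5 else pair[1]
        if rng.random() < model.D:
            calls[locus] = ()
        else:
            calls[locus] = (_miscall(allele, locus, table, model.e, rng),)
    return CellProfile(cell_id=cell_id, ploidy="haploid", calls=calls,
                       truth_contributor=genotype.contributor_id)


def assemble_mixture(
    contributors: list[GenotypeProfile],
    cell_counts: list[int],
    table: AlleleFrequencyTable,
    model: DropModel,
    rng: np.random.Generator,
    ploidy: str = "diploid",
) -> MixtureDataset:
    """Pool the stated numbers of cells per contributor into one shuffled dataset."""
    if len(contributors) != len(cell_counts):
        raise ValueError("cell_counts must have one entry per contributor")
    if any(c < 0 for c in cell_counts):
        raise ValueError("cell counts must be >= 0")
    simulate = simulate_diploid_cell if ploidy == "diploid" else simulate_haploid_cell
    cells: list[CellProfile] = []
    for genotype, count in zip(contributors, cell_counts):
        for _ in range(count):
            cells.append(simulate(genotype, table, model, rng))
    order = rng.permutation(len(cells))
    shuffled = tuple(
        CellProfile(
            cell_id=f"cell{i + 1:04d}",
            ploidy=cells[j].ploidy,
            calls=cells[j].calls,
            truth_contributor=cells[j].truth_contributor,
        )
        for i, j in enumerate(order)
    )
    return MixtureDataset(cells=shuffled, panel=table, truth=tuple(contributors))


def filter_cells(dataset: MixtureDataset, min_call_fraction: float) -> MixtureDataset:
    """Keep cells whose fraction of non-missing allele slots is >= the threshold."""
    if not (0.0 <= min_call_fraction <= 1.0):
        raise ValueError("min_call_fraction must be in [0, 1]")
    kept = tuple(c for c in dataset.cells if c.call_fraction() >= min_call_fraction)
    return MixtureDataset(cells=kept, panel=dataset.panel, truth=dataset.truth)


# ---------------------------------------------------------------------------
# ARFF serialization (minimal WEKA-compatible dialect)
# ---------------------------------------------------------------------------

def _slot_names(panel: AlleleFrequencyTable, ploidy: str) -> list[str]:
    if ploidy == "diploid":
        return [f"{locus}_{s}" for locus in panel.loci for s in (1, 2)]
    return list(panel.loci)


def _packed_slots(cell: CellProfile, panel: AlleleFrequencyTable) -> list[float | None]:
    per_locus = 2 if cell.ploidy == "diploid" else 1
    slots: list[float | None] = []
    for locus in panel.loci:
        obs = cell.calls.get(locus, ())
        slots.extend(list(obs) + [None] * (per_locus - len(obs)))
    return slots


def write_arff(dataset: MixtureDataset, path, relation: str = "single_cell_mixture") -> None:
    """Write the dataset as ARFF: one numeric attribute per allele slot, '?' missing.

    Cell identity and the hidden truth label are preserved in a ``%`` comment
    line preceding each data row, which WEKA ignores.
    """
    names = _slot_names(dataset.panel, dataset.ploidy)
    with open(path, "w") as fh:
        fh.write(f"@RELATION {relation}\n\n")
        for name in names:
            fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
        fh.write("\n@DATA\n")
        for cell in dataset.cells:
            truth = cell.truth_contributor if cell.truth_contributor is not None else ""
            fh.write(f"% cell_id={cell.cell_id} truth={truth}\n")
            values = [
                "?" if v is None else format_allele(v)
                for v in _packed_slots(cell, dataset.panel)
            ]
            fh.write(",".join(values) + "\n")


def read_arff(path, panel: AlleleFrequencyTable) -> MixtureDataset:
    """Read a dataset written by :func:`write_arff`, validating against ``panel``."""
    attributes: list[str] = []
    rows: list[tuple[str, str | None, list[float | None]]] = []
    in_data = False
    pending_id: str | None = None
    pending_truth: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("%"):
                meta = line[1:].strip()
                if meta.startswith("cell_id="):
                    parts = dict(
                        kv.split("=", 1) for kv in meta.split() if "=" in kv
                    )
                    pending_id = parts.get("cell_id")
                    pending_truth = parts.get("truth") or None
                continue
            lower = line.lower()
            if lower.startswith("@relation"):
                continue
            if lower.startswith("@attribute"):
                attributes.append(line.split()[1])
                continue
            if lower.startswith("@data"):
                in_data = True
                continue
            if in_data:
                values = [
                    None if tok.strip() == "?" else float(tok)
                    for tok in line.split(",")
                ]
                rows.append((pending_id or f"cell{len(rows) + 1:04d}", pending_truth, values))
                pending_id = pending_truth = None

    for ploidy in ("diploid", "haploid"):
        if attributes == _slot_names(panel, ploidy):
            break
    else:
        raise PanelError("ARFF attributes do not match the panel slot layout")
    per_locus = 2 if ploidy == "diploid" else 1

    cells = []
    for cell_id, truth, values in rows:
        if len(values) != per_locus * panel.n_loci:
            raise PanelError(f"cell {cell_id}: wrong number of attribute values")
        calls: dict[str, tuple[float, ...]] = {}
        for i, locus in enumerate(panel.loci):
            obs = [v for v in values[i * per_locus:(i + 1) * per_locus] if v is not None]
            for v in obs:
                if v not in panel.alleles(locus):
                    raise PanelError(
                        f"cell {cell_id}: allele {format_allele(v)} not in panel "
                        f"for locus {locus!r}"
                    )
            calls[locus] = tuple(sorted(obs))
        cells.append(CellProfile(cell_id=cell_id, ploidy=ploidy, calls=calls,
                                 truth_contributor=truth))
    return MixtureDataset(cells=tuple(cells), panel=panel, truth=None)


# ---------------------------------------------------------------------------
# Long-format CSV serialization
# ---------------------------------------------------------------------------

def write_profiles_csv(dataset: MixtureDataset, path) -> None:
    """Write cells as ``cell_id,locus,allele1,allele2`` (empty field = missing)."""
    with open(path, "w") as fh:
        fh.write("cell_id,locus,allele1,allele2\n")
        for cell in dataset.cells:
            for locus in dataset.panel.loci:
                obs = cell.calls.get(locus, ())
                a1 = format_allele(obs[0]) if len(obs) >= 1 else ""
                a2 = format_allele(obs[1]) if len(obs) >= 2 else ""
                fh.write(f"{cell.cell_id},{locus},{a1},{a2}\n")


def read_profiles_csv(path, panel: AlleleFrequencyTable, ploidy: str = "diploid") -> MixtureDataset:
    """Read a dataset from the long-format CSV written by :func:`write_profiles_csv`."""
    import csv

    per_cell: dict[str, dict[str, tuple[float, ...]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            cid = row["cell_id"]
            locus = row["locus"]
            obs = []
            for key in ("allele1", "allele2"):
                tok = (row.get(key) or "").strip()
                if tok:
                    obs.append(float(tok))
            per_cell.setdefault(cid, {})[locus] = tuple(sorted(obs))
    cells = []
    for cid, calls in per_cell.items():
        full = {locus: calls.get(locus, ()) for locus in panel.loci}
        cells.append(CellProfile(cell_id=cid, ploidy=ploidy, calls=full))
    return MixtureDataset(cells=tuple(cells), panel=panel, truth=None)
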