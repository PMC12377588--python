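"""Residue-level structural classification from AlphaFold pLDDT.

AlphaFold2's per-residue confidence (pLDDT, 0-100) correlates inversely with
structural flexibility: long stretches of low pLDDT are a good proxy for
intrinsically disordered regions (IDRs).  This module classifies every residue
of a protein as ``disordered``, ``intermediate`` or ``ordered``:

* **disordered** — pLDDT < 50 *and* the residue lies inside a contiguous
  low-confidence stretch of at least 30 residues with mean pLDDT < 70;
* **ordered** — pLDDT >= 70;
* **intermediate** — everything else (including short low-confidence dips,
  which are deliberately not called disordered to reduce false positives).

The stretch requirement is deliberately conservative: it targets extended
flexible linkers and regulatory regions rather than mobile loops inside
folded domains.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_DISORDERED = "disordered"
LABEL_INTERMEDIATE = "intermediate"
LABEL_ORDERED = "ordered"
REGION_LABELS = (LABEL_DISORDERED, LABEL_INTERMEDIATE, LABEL_ORDERED)


@dataclass(frozen=True)
class PlddtProfile:
    """One protein's ordered per-residue pLDDT values (0-100 scale).

    Positions are implicitly 1-based and contiguous: ``plddt[i]`` is the
    confidence of residue ``i + 1``.
    """

    protein_id: str
    plddt: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.plddt, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError(
                f"{self.protein_id}: pLDDT profile must be a non-empty 1-D sequence"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{self.protein_id}: pLDDT values must be finite")
        if arr.min() < 0.0 or arr.max() > 100.0:
            raise ValueError(
                f"{self.protein_id}: pLDDT values must lie in [0, 100]; "
                f"got range [{arr.min():g}, {arr.max():g}]"
            )
        object.__setattr__(self, "plddt", arr)

    @property
    def length(self) -> int:
        return int(self.plddt.size)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the disorder classifier.

    Defaults encode the standard pLDDT-based rule: disordered residues have
    pLDDT below ``disorder_plddt_max`` (strict) inside a contiguous stretch of
    at least ``stretch_min_len`` residues whose mean pLDDT is below
    ``stretch_mean_max`` (strict); ordered residues have pLDDT at least
    ``ordered_plddt_min`` (inclusive).

    ``stretch_mode`` selects how "contiguous stretch" is read:

    * ``maximal_run`` (default) — maximal runs of consecutive residues with
      pLDDT < ``stretch_mean_max``, kept when their length >=
      ``stretch_min_len``.  Short low-confidence dips flanked by confident
      structure stay intermediate, which matches the intent of the rule.
    * ``any_window`` — a residue qualifies if it lies in any window of exactly
      ``stretch_min_len`` residues whose mean pLDDT < ``stretch_mean_max``.
      More permissive; retained for sensitivity analysis.
    """

    disorder_plddt_max: float = 50.0
    stretch_min_len: int = 30
    stretch_mean_max: float = 70.0
    ordered_plddt_min: float = 70.0
    stretch_mode: str = "maximal_run"

    def __post_init__(self) -> None:
        if not (self.disorder_plddt_max <= self.stretch_mean_max <= 100.0):
            raise ValueError(
                "require disorder_plddt_max <= stretch_mean_max <= 100"
            )
        if not (0.0 < self.ordered_plddt_min <= 100.0):
            raise ValueError("ordered_plddt_min must be in (0, 100]")
        if self.stretch_min_len < 1:
            raise ValueError("stretch_min_len must be >= 1")
        if self.stretch_mode not in ("maximal_run", "any_window"):
            raise ValueError(
                f"unknown stretch_mode {self.stretch_mode!r}; "
                "expected 'maximal_run' or 'any_window'"
            )


@dataclass(frozen=True)
class DisorderSegment:
    """A contiguous low-confidence stretch (1-based, inclusive ends)."""

    protein_id: str
    start: int
    end: int
    mean_plddt: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ResidueAnnotation:
    protein_id: str
    position: int  # 1-based
    plddt: float
    label: str


@dataclass(frozen=True)
class ProteinDisorderSummary:
    protein_id: str
    n_residues: int
    fraction_disordered: float
    fraction_intermediate: float
    fraction_ordered: float
    has_disordered_region: bool
    highly_disordered: bool


@dataclass(frozen=True)
class ProteomeSummary:
    """Residue-weighted label fractions plus protein-level disorder rates."""

    n_proteins: int
    n_residues: int
    fraction_disordered: float
    fraction_intermediate: float
    fraction_ordered: float
    fraction_proteins_with_idr: float
    fraction_proteins_highly_disordered: float


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_plddt_table(path, rescale_fractional: bool = False) -> list[PlddtProfile]:
    """Read per-residue pLDDT from a TSV with columns protein_id, position, plddt.

    Rows of one protein must form a contiguous 1-based position range (they
    may appear unsorted).  If every value in the file is <= 1.0 and
    ``rescale_fractional`` is set, values are multiplied by 100 (some tools
    emit pLDDT on a 0-1 scale); without the flag such a file is rejected so
    unit errors cannot silently flip every classification.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "plddt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    values = df["plddt"].to_numpy(dtype=float)
    if np.all(values <= 1.0):
        if rescale_fractional:
            logger.warning(
                "%s: all pLDDT values <= 1.0; rescaling to 0-100", path
            )
            df = df.assign(plddt=values * 100.0)
        else:
            raise ValueError(
                f"{path}: all pLDDT values are <= 1.0 — looks like a 0-1 scale; "
                "pass rescale_fractional=True to rescale to 0-100"
            )
    if df["plddt"].min() < 0 or df["plddt"].max() > 100:
        bad = df.loc[(df["plddt"] < 0) | (df["plddt"] > 100)].iloc[0]
        raise ValueError(
            f"{path}: pLDDT {bad['plddt']} at {bad['protein_id']} position "
            f"{int(bad['position'])} outside [0, 100]"
        )

    profiles = []
    for protein_id, sub in df.groupby("protein_id", sort=True):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy(dtype=int)
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            gap = int(expected[pos != expected][0]) if len(pos) == len(expected) else int(
                np.setdiff1d(np.arange(1, pos.max() + 1), pos)[0]
            )
            raise ValueError(
                f"{path}: protein {protein_id} has a gap at position {gap} "
                "(positions must be contiguous from 1)"
            )
        profiles.append(PlddtProfile(str(protein_id), sub["plddt"].to_numpy(float)))
    return profiles


def read_plddt_from_structure(path, chain: str | None = None) -> PlddtProfile:
    """Extract a pLDDT profile from a PDB/mmCIF file (AlphaFold DB dialect).

    AlphaFold DB stores pLDDT in the B-factor field, identical for all atoms
    of a residue.  One value is taken per residue from its first atom; if a
    residue carries heterogeneous per-atom values the CA atom is used and a
    warning is logged.  Multi-chain files require an explicit ``chain``.
    """
    import biotite.structure as struc

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        import biotite.structure.io.pdbx as pdbx

        cif = pdbx.CIFFile.read(str(path))
        atoms = pdbx.get_structure(cif, model=1, extra_fields=["b_factor"])
    elif suffix in (".pdb", ".ent"):
        import biotite.structure.io.pdb as pdbio

        pdbf = pdbio.PDBFile.read(str(path))
        n_models = pdbio.get_model_count(pdbf)
        if n_models > 1:
            raise ValueError(
                f"{path}: {n_models} models found; multi-model files are not "
                "supported (AlphaFold DB files are single-model)"
            )
        atoms = pdbf.get_structure(model=1, extra_fields=["b_factor"])
    else:
        raise ValueError(f"{path}: unrecognised structure format {suffix!r}")

    if atoms.array_length() == 0:
        raise ValueError(f"{path}: empty structure")

    chains = np.unique(atoms.chain_id)
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"{path}: {len(chains)} chains found ({', '.join(chains)}); "
                "select one with the chain argument / --chain flag"
            )
        chain = str(chains[0])
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: chain {chain!r} not present")

    res_starts = struc.get_residue_starts(atoms)
    plddt = np.empty(len(res_starts), dtype=float)
    boundaries = np.append(res_starts, atoms.array_length())
    for i, (lo, hi) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        res_b = atoms.b_factor[lo:hi]
        if np.unique(res_b).size > 1:
            names = atoms.atom_name[lo:hi]
            ca = np.nonzero(names == "CA")[0]
            idx = lo + (ca[0] if ca.size else 0)
            logger.warning(
                "%s: residue %s has heterogeneous B-factors; using %s atom",
                path, atoms.res_id[lo], "CA" if ca.size else "first",
            )
            plddt[i] = atoms.b_factor[idx]
        else:
            plddt[i] = res_b[0]
    return PlddtProfile(path.stem, plddt)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def find_low_confidence_stretches(
    profile: PlddtProfile, params: ClassifierParams = ClassifierParams()
) -> list[DisorderSegment]:
    """Find the qualifying low-confidence stretches of a profile.

    In ``maximal_run`` mode these are the maximal runs of consecutive residues
    with pLDDT < ``stretch_mean_max`` of length >= ``stretch_min_len`` (their
    mean is then necessarily below the cutoff).  In ``any_window`` mode a
    residue qualifies if it lies in at least one window of exactly
    ``stretch_min_len`` residues whose mean is below the cutoff; the returned
    segments are the maximal unions of qualifying windows.  Segments are
    non-overlapping and sorted by start.
    """
    values = profile.plddt
    n = profile.length
    L = params.stretch_min_len
    cutoff = params.stretch_mean_max

    if params.stretch_mode == "maximal_run":
        low = values < cutoff
        member = np.zeros(n, dtype=bool)
        segments = []
        for start, end in _runs(low):
            if end - start + 1 >= L:
                mean = float(values[start : end + 1].mean())
                assert mean < cutoff, "run of values < cutoff must have mean < cutoff"
                segments.append(
                    DisorderSegment(profile.protein_id, int(start) + 1, int(end) + 1, mean)
                )
                member[start : end + 1] = True
        return segments

    # any_window: sliding means of exactly-L windows via cumulative sums
    if n < L:
        return []
    csum = np.concatenate([[0.0], np.cumsum(values)])
    window_means = (csum[L:] - csum[:-L]) / L  # window i covers [i, i+L-1]
    qualifying = window_means < cutoff
    covered = np.zeros(n, dtype=bool)
    for i in np.nonzero(qualifying)[0]:
        covered[i : i + L] = True
    segments = []
    for start, end in _runs(covered):
        mean = float(values[start : end + 1].mean())
        segments.append(DisorderSegment(profile.protein_id, int(start) + 1, int(end) + 1, mean))
    return segments


def _runs(mask: np.ndarray):
    """Yield (start, end) 0-based inclusive index pairs of True runs."""
    if mask.size == 0:
        return
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    yield from zip(starts, ends)


def classify_residues(
    profile: PlddtProfile, params: ClassifierParams = ClassifierParams()
) -> list[ResidueAnnotation]:
    """Assign each residue exactly one of the three structural labels."""
    labels = classify_labels(profile, params)
    return [
        ResidueAnnotation(profile.protein_id, i + 1, float(v), lab)
        for i, (v, lab) in enumerate(zip(profile.plddt, labels))
    ]


def classify_labels(
    profile: PlddtProfile, params: ClassifierParams = ClassifierParams()
) -> np.ndarray:
    """Vectorised classification: array of label strings, one per residue."""
    values = profile.plddt
    in_segment = np.zeros(profile.length, dtype=bool)
    for seg in find_low_confidence_stretches(profile, params):
        in_segment[seg.start - 1 : seg.end] = True
    labels = np.full(profile.length, LABEL_INTERMEDIATE, dtype=object)
    labels[values >= params.ordered_plddt_min] = LABEL_ORDERED
    labels[(values < params.disorder_plddt_max) & in_segment] = LABEL_DISORDERED
    return labels


def summarize_protein(annotations: list[ResidueAnnotation]) -> ProteinDisorderSummary:
    """Per-protein label fractions and disorder flags.

    ``highly_disordered`` means at least 30% of residues are disordered
    (boundary inclusive).
    """
    if not annotations:
        raise ValueError("cannot summarize an empty annotation list")
    protein_ids = {a.protein_id for a in annotations}
    if len(protein_ids) != 1:
        raise ValueError(f"annotations span multiple proteins: {sorted(protein_ids)}")
    n = len(annotations)
    counts = {lab: 0 for lab in REGION_LABELS}
    for a in annotations:
        counts[a.label] += 1
    fd = counts[LABEL_DISORDERED] / n
    return ProteinDisorderSummary(
        protein_id=annotations[0].protein_id,
        n_residues=n,
        fraction_disordered=fd,
        fraction_intermediate=counts[LABEL_INTERMEDIATE] / n,
        fraction_ordered=counts[LABEL_ORDERED] / n,
        has_disordered_region=counts[LABEL_DISORDERED] > 0,
        highly_disordered=fd >= 0.30,
    )


def summarize_proteome(summaries: list[ProteinDisorderSummary]) -> ProteomeSummary:
    """Residue-weighted fractions across proteins (not protein-averaged)."""
    if not summaries:
        raise ValueError("need at least one protein summary")
    n_res = sum(s.n_residues for s in summaries)
    wd = sum(s.fraction_disordered * s.n_residues for s in summaries) / n_res
    wi = sum(s.fraction_intermediate * s.n_residues for s in summaries) / n_res
    wo = sum(s.fraction_ordered * s.n_residues for s in summaries) / n_res
    n_prot = len(summaries)
    return ProteomeSummary(
        n_proteins=n_prot,
        n_residues=n_res,
        fraction_disordered=wd,
        fraction_intermediate=wi,
        fraction_ordered=wo,
        fraction_proteins_with_idr=sum(s.has_disordered_region for s in summaries) / n_prot,
        fraction_proteins_highly_disordered=sum(s.highly_disordered for s in summaries) / n_prot,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def annotations_to_frame(annotations: list[ResidueAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in annotations],
            "position": [a.position for a in annotations],
            "plddt": [a.plddt for a in annotations],
            "label": [a.label for a in annotations],
        }
    )


def write_annotations(annotations: list[ResidueAnnotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def write_segments(segments: list[DisorderSegment], path) -> None:
    """Segment TSV with 1-based inclusive coordinates (unlike genomic BED)."""
    pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "mean_plddt": [s.mean_plddt for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def write_proteome_summary(summary: ProteomeSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.__dict__, fh, indent=2)
        fh.write("\n")
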