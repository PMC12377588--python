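"""Missense variant tables: loading, collagen exclusion, region assignment,
and region-distribution / enrichment statistics.

Variants carry a class label (ClinVar pathogenic, ClinVar benign, or gnomAD
putatively benign), optional inheritance mode (AD/AR) and molecular mechanism
(LOF/GOF/DN) annotations, and — after joining against a residue annotation
set — a structural region label.  The canonical in-memory container is a
pandas DataFrame with one row per variant.

Collagen genes are excluded up front: collagen-helix proteins are fibrous,
not intrinsically disordered, yet their low pLDDT makes them look disordered
and they would otherwise dominate the disordered pathogenic class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .structure import REGION_LABELS

logger = logging.getLogger(__name__)

CLASS_LABELS = ("clinvar_pathogenic", "clinvar_benign", "gnomad_benign")
INHERITANCE_LABELS = ("AD", "AR", "unknown")
MECHANISM_LABELS = ("LOF", "GOF", "DN", "unknown")
REGION_UNASSIGNED = "unassigned"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

REQUIRED_COLUMNS = ("protein_id", "gene", "position", "ref_aa", "alt_aa", "class_label")


@dataclass(frozen=True)
class EnrichmentResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    ``odds_ratio`` is the sample odds ratio (a*d)/(b*c), infinite when
    b*c == 0 with a*d > 0, and None (flagged ``degenerate``) when a margin of
    the table is zero, in which case p = 1.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float | None
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class BinomialCI:
    k: int
    n: int
    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "wilson"


# ---------------------------------------------------------------------------
# loading & filtering
# ---------------------------------------------------------------------------

def load_variants(path) -> pd.DataFrame:
    """Load and validate a missense-variant TSV.

    Required columns: protein_id, gene, position, ref_aa, alt_aa, class_label;
    optional: inheritance, mechanism (filled with "unknown" when absent).
    Exact duplicates of (protein_id, position, alt_aa, class_label) are
    dropped with a logged count.  A ``region`` column is added, initialised to
    "unassigned".
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    for optional in ("inheritance", "mechanism"):
        if optional not in df.columns:
            df[optional] = "unknown"
        df[optional] = df[optional].fillna("unknown")

    _validate_enum(df, "class_label", CLASS_LABELS, path)
    _validate_enum(df, "inheritance", INHERITANCE_LABELS, path)
    _validate_enum(df, "mechanism", MECHANISM_LABELS, path)

    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        if row.ref_aa == row.alt_aa:
            raise ValueError(
                f"{path} line {idx}: ref_aa == alt_aa ({row.ref_aa}) — not a missense variant"
            )
        if row.ref_aa not in AMINO_ACIDS or row.alt_aa not in AMINO_ACIDS:
            raise ValueError(
                f"{path} line {idx}: amino acids must be single letters from the "
                f"20-letter alphabet; got {row.ref_aa!r}/{row.alt_aa!r}"
            )
        if row.position < 1:
            raise ValueError(f"{path} line {idx}: position must be >= 1")

    key = ["protein_id", "position", "alt_aa", "class_label"]
    n_before = len(df)
    df = df.drop_duplicates(subset=key, keep="first").reset_index(drop=True)
    if len(df) < n_before:
        logger.info("%s: dropped %d duplicate variant rows", path, n_before - len(df))

    cross = df.duplicated(subset=["protein_id", "position", "alt_aa"], keep=False)
    n_cross = int(cross.sum())
    if n_cross:
        logger.warning(
            "%s: %d variants appear under more than one class label (kept, not resolved)",
            path, n_cross,
        )

    df["region"] = REGION_UNASSIGNED
    return df


def _validate_enum(df: pd.DataFrame, column: str, allowed: tuple, path) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header is line 1
        raise ValueError(
            f"{path} line {row}: invalid {column} {df.loc[bad, column].iloc[0]!r}; "
            f"allowed values: {', '.join(allowed)}"
        )


def load_exclusion_list(path) -> set[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                genes.add(token.casefold())
    return genes


def exclude_genes(df: pd.DataFrame, exclusion: set[str]) -> tuple[pd.DataFrame, dict]:
    """Remove variants in excluded genes (case-folded exact symbol match).

    Returns the filtered frame and a report of removed counts per class label.
    An empty exclusion list passes everything through with a warning.
    """
    if not exclusion:
        logger.warning("empty gene exclusion list: no variants removed")
        return df.copy(), {"removed_total": 0, "removed_per_class": {}}
    folded = {g.casefold() for g in exclusion}
    mask = df["gene"].str.casefold().isin(folded)
    removed = df.loc[mask]
    n_casefold = int((mask & ~df["gene"].isin(exclusion)).sum())
    if n_casefold:
        logger.info("%d variants matched the exclusion list only after case-folding", n_casefold)
    report = {
        "removed_total": int(mask.sum()),
        "removed_per_class": removed["class_label"].value_counts().to_dict(),
    }
    return df.loc[~mask].reset_index(drop=True), report


def assign_regions(
    df: pd.DataFrame, annotations: pd.DataFrame, strict: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Copy each variant's structural region from the residue annotations.

    ``annotations`` is the residue annotation table (protein_id, position,
    label).  Variants on proteins or positions without an annotation stay
    "unassigned" (an error in strict mode).
    """
    if (df["position"] < 1).any():
        raise ValueError("variant positions must be >= 1")
    lookup = annotations.set_index(["protein_id", "position"])["label"]
    keys = pd.MultiIndex.from_frame(df[["protein_id", "position"]])
    assigned = lookup.reindex(keys).to_numpy(dtype=object)
    out = df.copy()
    out["region"] = np.where(pd.isna(assigned), REGION_UNASSIGNED, assigned)
    n_unassigned = int((out["region"] == REGION_UNASSIGNED).sum())
    if n_unassigned and strict:
        raise ValueError(
            f"{n_unassigned} variants have no residue annotation (strict mode)"
        )
    if n_unassigned:
        logger.info("%d variants left unassigned (no pLDDT coverage)", n_unassigned)
    return out, {"n_assigned": len(out) - n_unassigned, "n_unassigned": n_unassigned}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def region_distribution(df: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Counts and proportions of variants per structural region, per stratum.

    ``by`` lists grouping columns (e.g. ["class_label"] or
    ["class_label", "inheritance"]); None means one global stratum.
    Unassigned variants are excluded with a logged count.  For an empty
    stratum the proportions are NaN and ``undefined`` is flagged.
    """
    unassigned = df["region"] == REGION_UNASSIGNED
    if unassigned.any():
        logger.info("region_distribution: excluding %d unassigned variants", int(unassigned.sum()))
    data = df.loc[~unassigned]
    by = list(by) if by else []

    if by:
        groups = data.groupby(by, observed=False)
        strata = [(k if isinstance(k, tuple) else (k,), g) for k, g in groups]
    else:
        strata = [((), data)]

    rows = []
    for key, g in strata:
        counts = g["region"].value_counts()
        total = int(counts.sum())
        for region in REGION_LABELS:
            c = int(counts.get(region, 0))
            rows.append(
                dict(zip(by, key))
                | {
                    "region": region,
                    "count": c,
                    "proportion": c / total if total else math.nan,
                    "undefined": total == 0,
                }
            )
    return pd.DataFrame(rows)


def fisher_exact_2x2(table) -> EnrichmentResult:
    """Two-sided Fisher's exact test (minimum-likelihood rule).

    The p-value sums hypergeometric probabilities, at fixed margins, of all
    tables whose probability does not exceed the observed table's.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    tab = ((a, b), (c, d))
    margins = (a + b, c + d, a + c, b + d)
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be nonzero")
    if 0 in margins:
        return EnrichmentResult(tab, None, 1.0, degenerate=True)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        oddsr = math.inf if a * d > 0 else math.nan
    else:
        oddsr = (a * d) / (b * c)
    return EnrichmentResult(tab, oddsr, float(p))


def binomial_ci(k: int, n: int, level: float = 0.95, method: str = "wilson") -> BinomialCI:
    """Binomial proportion confidence interval (Wilson score by default;
    ``clopper-pearson`` available)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lower, upper = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    # both methods give exactly 0 / 1 at the extremes; undo float round-off
    if k == 0:
        lower = 0.0
    if k == n:
        upper = 1.0
    return BinomialCI(k, n, k / n, float(lower), float(upper), level, method)


def write_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
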