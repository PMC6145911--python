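"""Plate normalization, z-scoring, significance testing and hit calling.

Normalization and hit criteria
------------------------------
Per plate, cell number and per-cell ALP activity are expressed as a
percentage of the mean of that plate's Non-Targeting (NT) control wells.
Per-plate standardization additionally uses the z-score of the binary
logarithm (log2) of ALP per cell.  A gene, measured in replicate plates,
becomes a hit when all of the following hold:

* viability: mean cell number >= 60% of NT (below 60% the well is excluded
  as a viability casualty, the Kif11 transfection-control archetype);
* effect size: mean ALP activity >= 160% (suppressor of differentiation:
  its knockdown raises ALP) or <= 40% (activator) of NT;
* significance: unpaired homoscedastic two-tailed t-test of the gene's
  log2 values against the NT wells, p < 0.05 (unadjusted by default; a
  Benjamini-Hochberg option exists);
* robustness: mean z-score at least 1.0 above (suppressor) or below
  (activator) the NT wells' mean z-score.

The t-test compares log2 percent-of-control values so that plate offsets
cancel; this equals log2 ALP re-centred by each plate's NT log2 mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import PlateLayout, Role, WellMeasurement

__all__ = [
    "NormalizedWell",
    "GeneResult",
    "HitCategory",
    "HitThresholds",
    "HitCall",
    "NormalizationError",
    "normalize_to_nt",
    "zscore_log2",
    "test_vs_nt",
    "aggregate_genes",
    "call_hits",
    "classify_table",
    "load_candidate_table",
    "hit_table",
]

#: Roles included in the per-plate z-score pool by default: library wells
#: carry the screened distribution, NT wells anchor it.  Kif11, mock and
#: untreated wells are excluded (they are process controls, not treatments
#: on the ALP scale); positive controls are excluded as known extremes.
DEFAULT_Z_ROLES = frozenset({Role.LIBRARY, Role.NON_TARGETING})


class NormalizationError(ValueError):
    """Raised when a plate cannot be normalized (no usable NT wells)."""


@dataclass
class NormalizedWell:
    """One well on the percent-of-control and log2/z scales."""

    plate_id: str
    well: str
    gene_symbol: str
    role: Role
    pct_cell_number: float
    pct_alp: float | None
    log2_alp: float | None
    z_alp: float | None = None
    zero_alp_imputed: bool = False


@dataclass
class GeneResult:
    """Replicate-aggregated result for one gene."""

    gene_symbol: str
    mean_pct_cell_number: float
    mean_pct_alp: float
    mean_z_alp: float | None
    p_value: float | None
    n_replicates: int


class HitCategory(str, Enum):
    SUPPRESSOR = "suppressor"
    ACTIVATOR = "activator"
    EXCLUDED_VIABILITY = "excluded_viability"
    NOT_HIT = "not_hit"


@dataclass(frozen=True)
class HitThresholds:
    """Hit-calling cut-offs on the percent-of-NT and z scales."""

    viability_min_pct: float = 60.0
    alp_high_pct: float = 160.0
    alp_low_pct: float = 40.0
    p_max: float = 0.05
    z_margin: float = 1.0
    adjust_p: bool = False  # Benjamini-Hochberg across genes when True


@dataclass
class HitCall:
    gene_symbol: str
    category: HitCategory
    passed_viability: bool
    passed_alp_threshold: bool
    passed_p: bool
    passed_z: bool


# ---------------------------------------------------------------------------
# normalization

def normalize_to_nt(
    wells: Sequence[WellMeasurement], layout: PlateLayout | None = None
) -> list[NormalizedWell]:
    """Express each well as a percentage of its plate's Non-Targeting mean.

    Cell number and ALP per cell are normalized separately.  log2 ALP is
    attached per well; wells with zero ALP receive half the smallest
    positive ALP value on the plate as a pseudocount before the log and are
    flagged.  Raises :class:`NormalizationError` when a plate has no NT
    wells with a defined ALP value or a zero NT mean.
    """
    out: list[NormalizedWell] = []
    by_plate: dict[str, list[WellMeasurement]] = {}
    for m in wells:
        by_plate.setdefault(m.plate_id, []).append(m)
    for plate_id, plate_wells in by_plate.items():
        nt = [m for m in plate_wells if m.role == Role.NON_TARGETING]
        nt_alp = [m.alp_per_cell for m in nt if m.alp_per_cell is not None]
        if not nt_alp:
            raise NormalizationError(
                f"plate {plate_id!r} has no non_targeting wells with ALP values"
            )
        nt_cell_mean = float(np.mean([m.cell_number for m in nt]))
        nt_alp_mean = float(np.mean(nt_alp))
        if nt_cell_mean == 0 or nt_alp_mean == 0:
            raise NormalizationError(f"plate {plate_id!r}: non-targeting mean is zero")
        positives = [
            m.alp_per_cell
            for m in plate_wells
            if m.alp_per_cell is not None and m.alp_per_cell > 0
        ]
        pseudocount = 0.5 * min(positives) if positives else None
        for m in plate_wells:
            if m.alp_per_cell is None:
                pct_alp = log2_alp = None
                imputed = False
            else:
                pct_alp = 100.0 * m.alp_per_cell / nt_alp_mean
                if m.alp_per_cell > 0:
                    log2_alp = math.log2(m.alp_per_cell)
                    imputed = False
                elif pseudocount is not None:
                    log2_alp = math.log2(pseudocount)
                    imputed = True
                else:
                    log2_alp = None
                    imputed = False
            out.append(
                NormalizedWell(
                    plate_id=plate_id,
                    well=m.well,
                    gene_symbol=m.gene_symbol,
                    role=m.role,
                    pct_cell_number=100.0 * m.cell_number / nt_cell_mean,
                    pct_alp=pct_alp,
                    log2_alp=log2_alp,
                    zero_alp_imputed=imputed,
                )
            )
    return out


def zscore_log2(
    wells: Sequence[NormalizedWell],
    include_roles: frozenset[Role] | set[Role] = DEFAULT_Z_ROLES,
) -> tuple[list[NormalizedWell], dict[str, float]]:
    """Per-plate z-score of log2 ALP over the included wells.

    Fills ``z_alp`` in place on included wells and returns the wells plus a
    mapping ``plate_id -> z_NT`` (the NT wells' mean z), the reference
    point of the z hit criterion.  Raises on plates with fewer than two
    included wells or zero variance.
    """
    z_nt: dict[str, float] = {}
    by_plate: dict[str, list[NormalizedWell]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, []).append(w)
    for plate_id, plate_wells in by_plate.items():
        included = [
            w for w in plate_wells if w.role in include_roles and w.log2_alp is not None
        ]
        if len(included) < 2:
            raise NormalizationError(
                f"plate {plate_id!r}: fewer than 2 wells available for z-scoring"
            )
        vals = np.array([w.log2_alp for w in included])
        sd = vals.std(ddof=1)
        if sd == 0:
            raise NormalizationError(f"plate {plate_id!r}: zero variance in log2 ALP")
        mean = vals.mean()
        for w in included:
            w.z_alp = float((w.log2_alp - mean) / sd)
        nt_z = [w.z_alp for w in included if w.role == Role.NON_TARGETING]
        if not nt_z:
            raise NormalizationError(f"plate {plate_id!r}: no NT wells in z pool")
        z_nt[plate_id] = float(np.mean(nt_z))
    return list(wells), z_nt


# ---------------------------------------------------------------------------
# significance

def test_vs_nt(
    gene_values: Sequence[float], nt_values: Sequence[float]
) -> float:
    """Unpaired homoscedastic (pooled-variance) two-tailed t-test p-value.

    Degenerate inputs: two identical constant groups give p = 1; two
    different constant groups give p approaching 0 (reported as the
    smallest positive float, with a warning).
    """
    x = np.asarray(gene_values, dtype=float)
    y = np.asarray(nt_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return 1.0
        warnings.warn("both groups constant but different; p-value degenerate at 0")
        return float(np.nextafter(0.0, 1.0))
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.pvalue)


def aggregate_genes(
    wells: Sequence[NormalizedWell],
    z_nt: Mapping[str, float] | None = None,
) -> list[GeneResult]:
    """Aggregate normalized wells into per-gene replicate results.

    The p-value tests each gene's log2 percent-of-control values (one per
    replicate plate) against the pooled NT wells' values on the same scale;
    it is ``None`` for genes with fewer than two usable replicates.
    """
    nt_log2pct = [
        math.log2(w.pct_alp / 100.0)
        for w in wells
        if w.role == Role.NON_TARGETING and w.pct_alp is not None and w.pct_alp > 0
    ]
    by_gene: dict[str, list[NormalizedWell]] = {}
    for w in wells:
        if w.role in (Role.LIBRARY, Role.POSITIVE_CONTROL, Role.KIF11_CONTROL) and w.gene_symbol:
            by_gene.setdefault(w.gene_symbol, []).append(w)
    out = []
    for gene, grp in sorted(by_gene.items()):
        pct_alp = [w.pct_alp for w in grp if w.pct_alp is not None]
        zs = [w.z_alp for w in grp if w.z_alp is not None]
        log2pct = [
            math.log2(w.pct_alp / 100.0)
            for w in grp
            if w.pct_alp is not None and w.pct_alp > 0
        ]
        p = None
        if len(log2pct) >= 2 and len(nt_log2pct) >= 2:
            p = test_vs_nt(log2pct, nt_log2pct)
        out.append(
            GeneResult(
                gene_symbol=gene,
                mean_pct_cell_number=float(np.mean([w.pct_cell_number for w in grp])),
                mean_pct_alp=float(np.mean(pct_alp)) if pct_alp else float("nan"),
                mean_z_alp=float(np.mean(zs)) if zs else None,
                p_value=p,
                n_replicates=len(grp),
            )
        )
    return out


# ---------------------------------------------------------------------------
# hit calling

def call_hits(
    results: Sequence[GeneResult],
    thresholds: HitThresholds = HitThresholds(),
    z_nt: float = 0.0,
) -> list[HitCall]:
    """Apply the three-criterion hit classification to gene results.

    ``z_nt`` is the NT wells' mean z-score (averaged over plates); the z
    criterion requires the gene's mean z to clear ``z_nt +/- z_margin``.
    Genes below the viability cut-off are ``excluded_viability`` regardless
    of their ALP readout; genes with a missing p-value cannot pass the p
    criterion and fall through to ``not_hit``.
    """
    p_values = {r.gene_symbol: r.p_value for r in results}
    if thresholds.adjust_p:
        from statsmodels.stats.multitest import multipletests

        genes = [g for g, p in p_values.items() if p is not None]
        if genes:
            _, adj, _, _ = multipletests(
                [p_values[g] for g in genes], method="fdr_bh"
            )
            p_values.update(dict(zip(genes, adj)))
    calls = []
    for r in results:
        passed_viability = r.mean_pct_cell_number >= thresholds.viability_min_pct
        up = not math.isnan(r.mean_pct_alp) and r.mean_pct_alp >= thresholds.alp_high_pct
        down = not math.isnan(r.mean_pct_alp) and r.mean_pct_alp <= thresholds.alp_low_pct
        passed_alp = up or down
        p = p_values.get(r.gene_symbol)
        passed_p = p is not None and p < thresholds.p_max
        z = r.mean_z_alp
        passed_z = z is not None and (
            (up and z >= z_nt + thresholds.z_margin)
            or (down and z <= z_nt - thresholds.z_margin)
        )
        if not passed_viability:
            cat = HitCategory.EXCLUDED_VIABILITY
        elif passed_alp and passed_p and passed_z:
            cat = HitCategory.SUPPRESSOR if up else HitCategory.ACTIVATOR
        else:
            cat = HitCategory.NOT_HIT
        calls.append(
            HitCall(
                gene_symbol=r.gene_symbol,
                category=cat,
                passed_viability=passed_viability,
                passed_alp_threshold=passed_alp,
                passed_p=passed_p,
                passed_z=passed_z,
            )
        )
    return calls


def classify_table(
    rows: pd.DataFrame,
    thresholds: HitThresholds = HitThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify candidate rows carrying (gene, ALP %, p-value upper bound).

    Applies only the ALP-threshold and p criteria — candidate tables are
    post viability/z filtering, so those criteria are taken as passed.
    Returns the classified table and per-category gene counts.
    """
    required = {"gene_symbol", "pct_alp", "p_bound"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    cats = []
    for _, row in rows.iterrows():
        pct = float(row["pct_alp"])
        p_ok = float(row["p_bound"]) <= thresholds.p_max
        if pct >= thresholds.alp_high_pct and p_ok:
            cats.append(HitCategory.SUPPRESSOR.value)
        elif pct <= thresholds.alp_low_pct and p_ok:
            cats.append(HitCategory.ACTIVATOR.value)
        else:
            cats.append(HitCategory.NOT_HIT.value)
    table = rows.copy()
    table["category"] = cats
    counts = {c.value: 0 for c in HitCategory}
    counts.pop(HitCategory.EXCLUDED_VIABILITY.value)
    for c in cats:
        counts[c] += 1
    return table, counts


def load_candidate_table() -> pd.DataFrame:
    """The 65 candidate genes of the primary screen.

    Columns: ``gene_symbol``, ``pct_alp`` (ALP activity per cell as % of
    the Non-Targeting control) and ``p_bound`` (the reported p-value upper
    bound).  These rows passed the viability and z filters of the screen
    and serve as the classification fixture for the ALP/p criteria.
    """
    with resources.files("osteoscreen.data").joinpath(
        "primary_screen_candidates.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def hit_table(
    results: Sequence[GeneResult], calls: Sequence[HitCall]
) -> pd.DataFrame:
    """Join gene results and hit calls into the exportable hit table."""
    by_gene = {c.gene_symbol: c for c in calls}
    rows = []
    for r in results:
        c = by_gene[r.gene_symbol]
        rows.append(
            {
                "gene_symbol": r.gene_symbol,
                "mean_pct_cell_number": r.mean_pct_cell_number,
                "mean_pct_alp": r.mean_pct_alp,
                "mean_z_alp": r.mean_z_alp,
                "p_value": r.p_value,
                "category": c.category.value,
                "passed_viability": c.passed_viability,
                "passed_alp_threshold": c.passed_alp_threshold,
                "passed_p": c.passed_p,
                "passed_z": c.passed_z,
            }
        )
    return pd.DataFrame(rows).sort_values("gene_symbol", kind="stable").reset_index(drop=True)
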