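"""Fluorescence binding-assay normalization and relative binding scores.

GFP-RBP fusion proteins are incubated with lactococcal strains in 96-well
plates; bound fluorescence reports receptor recognition.  Raw readings are
converted to fluorescence units (FU) by subtracting the mean of the RBP's
protein-only control wells and dividing by the well's OD600:

    FU = max(0, (raw − control_mean) / OD600)

Negative differences are clamped to zero (a deficit below the no-cell
control is noise) and the clamp is flagged.  For each RBP the *optimal host*
is the strain with the highest mean FU across replicates, and every
strain's relative binding-affinity score is its mean FU as a percentage of
the optimal host's.  Strain pairs are compared with Welch's unequal-variance
two-sample t-test on replicate FU values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class PlateConfigurationError(ValueError):
    """Raised when an RBP has no control wells or a well is malformed."""


class InsufficientReplicatesError(ValueError):
    """Raised when a strain comparison has fewer than 2 replicates."""


@dataclass(frozen=True)
class PlateMeasurement:
    """One well: a sample (RBP × strain) or an RBP-only control."""

    rbp_id: str
    replicate: int
    raw_fluorescence: float
    strain_id: str | None = None
    od600: float | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.raw_fluorescence < 0:
            raise PlateConfigurationError(
                f"well ({self.rbp_id}, {self.strain_id}): negative raw fluorescence"
            )
        if self.is_control:
            if self.strain_id is not None or self.od600 is not None:
                raise PlateConfigurationError(
                    f"control well for {self.rbp_id!r} must have no strain and no OD600"
                )
        else:
            if self.strain_id is None or self.od600 is None:
                raise PlateConfigurationError(
                    f"sample well for {self.rbp_id!r} needs both strain_id and od600"
                )


@dataclass(frozen=True)
class NormalizedFU:
    rbp_id: str
    strain_id: str
    replicate: int
    fu: float
    clamped: bool = False


@dataclass
class BindingMatrix:
    """Per-(RBP, strain) FU summary, relative scores and pairwise p-values."""

    summary: pd.DataFrame  # index (rbp_id, strain_id): mean_fu, sd_fu, n, relative_score_pct, optimal_host, no_binding
    p_values: pd.DataFrame  # rbp_id, strain_a, strain_b, p_value, zero_variance

    def score_matrix(self) -> pd.DataFrame:
        """Wide RBP × strain matrix of relative binding scores."""
        return (
            self.summary.reset_index()
            .pivot(index="rbp_id", columns="strain_id", values="relative_score_pct")
            .sort_index()
        )


def control_means(wells: list[PlateMeasurement]) -> dict[str, float]:
    """Mean control-well fluorescence per RBP; every RBP must have ≥1 control."""
    controls: dict[str, list[float]] = {}
    rbps = set()
    for w in wells:
        rbps.add(w.rbp_id)
        if w.is_control:
            controls.setdefault(w.rbp_id, []).append(w.raw_fluorescence)
    missing = rbps - set(controls)
    if missing:
        raise PlateConfigurationError(
            f"no control wells for RBP(s): {sorted(missing)}"
        )
    return {rbp: float(np.mean(v)) for rbp, v in controls.items()}


def normalize_fu(well: PlateMeasurement, control_mean: float) -> NormalizedFU:
    """FU = max(0, (raw − control_mean) / OD600); clamping is recorded."""
    if well.is_control:
        raise PlateConfigurationError("control wells are not normalised")
    assert well.strain_id is not None and well.od600 is not None
    if well.od600 <= 0:
        raise PlateConfigurationError(
            f"well ({well.rbp_id}, {well.strain_id}): OD600 must be positive"
        )
    value = (well.raw_fluorescence - control_mean) / well.od600
    return NormalizedFU(
        rbp_id=well.rbp_id,
        strain_id=well.strain_id,
        replicate=well.replicate,
        fu=max(0.0, value),
        clamped=value < 0,
    )


def normalize_plate(wells: list[PlateMeasurement]) -> list[NormalizedFU]:
    means = control_means(wells)
    return [normalize_fu(w, means[w.rbp_id]) for w in wells if not w.is_control]


def _fu_frame(fus: list[NormalizedFU]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rbp_id": [f.rbp_id for f in fus],
            "strain_id": [f.strain_id for f in fus],
            "replicate": [f.replicate for f in fus],
            "fu": [f.fu for f in fus],
        }
    )


def relative_binding_score(fus: list[NormalizedFU], rbp_id: str) -> pd.Series:
    """Per-strain relative score for one RBP: 100 · mean FU / optimal-host mean FU.

    The optimal host is the strain with the highest mean FU (ties to the
    smallest strain id).  When every strain's mean is zero the RBP shows no
    binding: all scores are NaN and the caller should consult the
    ``no_binding`` flag rather than treat any strain as a host.
    """
    df = _fu_frame(fus)
    df = df[df.rbp_id == rbp_id]
    if df.empty:
        raise ValueError(f"no FU rows for RBP {rbp_id!r}")
    means = df.groupby("strain_id").fu.mean().sort_index()
    best = means.max()
    if best == 0:
        return pd.Series(np.nan, index=means.index, name="relative_score_pct")
    return (100.0 * means / best).rename("relative_score_pct")


def compare_strains(
    fus: list[NormalizedFU], rbp_id: str, strain_a: str, strain_b: str
) -> tuple[float, bool]:
    """Welch's two-sided t-test p-value on replicate FU, plus a zero-variance flag.

    Degenerate cases: identical replicate vectors give p = 1; zero variance
    in both groups with different means gives p = 0 with the flag set.
    """
    df = _fu_frame(fus)
    xa = df[(df.rbp_id == rbp_id) & (df.strain_id == strain_a)].fu.to_numpy()
    xb = df[(df.rbp_id == rbp_id) & (df.strain_id == strain_b)].fu.to_numpy()
    if len(xa) < 2 or len(xb) < 2:
        raise InsufficientReplicatesError(
            f"need >=2 replicates per strain for {rbp_id!r}: "
            f"{strain_a!r} has {len(xa)}, {strain_b!r} has {len(xb)}"
        )
    if np.var(xa) == 0 and np.var(xb) == 0:
        return (1.0, True) if np.mean(xa) == np.mean(xb) else (0.0, True)
    p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
    return p, False


def binding_matrix(fus: list[NormalizedFU], alpha: float = 0.01) -> BindingMatrix:
    """Assemble the RBP × strain affinity summary and pairwise comparisons."""
    df = _fu_frame(fus)
    if df.empty:
        raise ValueError("no normalised FU values")
    rows = []
    pv_rows = []
    for rbp, sub in df.groupby("rbp_id"):
        means = sub.groupby("strain_id").fu.agg(["mean", "std", "count"]).sort_index()
        no_binding = bool((means["mean"] == 0).all())
        if no_binding:
            optimal = None
            scores = pd.Series(np.nan, index=means.index)
        else:
            # idxmax on a sorted index breaks ties toward the smallest strain id
            optimal = means["mean"].idxmax()
            scores = 100.0 * means["mean"] / means.loc[optimal, "mean"]
        for strain in means.index:
            rows.append(
                {
                    "rbp_id": rbp,
                    "strain_id": strain,
                    "mean_fu": means.loc[strain, "mean"],
                    "sd_fu": means.loc[strain, "std"],
                    "n": int(means.loc[strain, "count"]),
                    "relative_score_pct": scores.loc[strain],
                    "optimal_host": strain == optimal,
                    "no_binding": no_binding,
                }
            )
        replicate_counts = sub.groupby("strain_id").fu.count()
        for sa, sb in combinations(sorted(means.index), 2):
            if replicate_counts[sa] < 2 or replicate_counts[sb] < 2:
                continue
            p, zero_var = compare_strains(fus, rbp, sa, sb)
            pv_rows.append(
                {
                    "rbp_id": rbp,
                    "strain_a": sa,
                    "strain_b": sb,
                    "p_value": p,
                    "significant": p < alpha,
                    "zero_variance": zero_var,
                }
            )
    summary = pd.DataFrame(rows).set_index(["rbp_id", "strain_id"]).sort_index()
    p_values = pd.DataFrame(
        pv_rows, columns=["rbp_id", "strain_a", "strain_b", "p_value", "significant", "zero_variance"]
    )
    return BindingMatrix(summary=summary, p_values=p_values)


# ---------------------------------------------------------------------------
# Plate TSV I/O
#
# Columns: rbp_id, strain_id (empty for controls), replicate,
# raw_fluorescence, od600 (empty for controls), is_control.

def read_plate_tsv(path: str | Path) -> list[PlateMeasurement]:
    df = pd.read_csv(path, sep="\t", dtype={"rbp_id": str, "strain_id": str})
    required = {"rbp_id", "strain_id", "replicate", "raw_fluorescence", "od600", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise PlateConfigurationError(f"plate TSV missing columns: {sorted(missing)}")
    wells = []
    for _, row in df.iterrows():
        is_control = bool(row.is_control)
        strain = None if (is_control or pd.isna(row.strain_id)) else str(row.strain_id)
        od = None if (is_control or pd.isna(row.od600)) else float(row.od600)
        if not is_control and (strain is None or od is None):
            raise PlateConfigurationError(
                f"sample well for RBP {row.rbp_id!r} replicate {row.replicate} "
                "is missing strain_id or od600"
            )
        wells.append(
            PlateMeasurement(
                rbp_id=str(row.rbp_id),
                strain_id=strain,
                replicate=int(row.replicate),
                raw_fluorescence=float(row.raw_fluorescence),
                od600=od,
                is_control=is_control,
            )
        )
    return wells


def write_plate_tsv(wells: list[PlateMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "rbp_id": [w.rbp_id for w in wells],
            "strain_id": [w.strain_id if w.strain_id is not None else "" for w in wells],
            "replicate": [w.replicate for w in wells],
            "raw_fluorescence": [f"{w.raw_fluorescence:.6f}" for w in wells],
            "od600": ["" if w.od600 is None else f"{w.od600:.6f}" for w in wells],
            "is_control": [int(w.is_control) for w in wells],
        }
    ).to_csv(path, sep="\t", index=False)
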