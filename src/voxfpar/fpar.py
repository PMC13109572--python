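"""Ground-truth fPAR from six-component quantum-sensor readings.

The field protocol measures incident and reflected PAR at three heights
(canopy top, mid-canopy, base) in four cardinal directions per tree. This
module averages directions, computes absorbed PAR and fPAR, derives the
per-stratum labels, and writes them onto fused voxel tables.

Two whole-canopy balances are provided:

* ``paper`` (default) — APAR = PAR_ci − PAR_cr − (PAR_gi − PAR_gr)
  − (PAR_mi − PAR_mr): the as-published three-layer balance, which
  subtracts both the middle and ground net fluxes from the top net flux.
  For strongly transmitting canopies it can go negative; such records are
  flagged invalid rather than clipped.
* ``two_layer`` — APAR = (PAR_ci − PAR_cr) − (PAR_gi − PAR_gr): the
  standard radiative balance between the top and base levels, always in
  [0, 1] for physically ordered components.

Per-stratum fPAR uses the net-flux differences between adjacent sensor
levels: with net fluxes F_c, F_m, F_g (incident minus reflected at top,
middle, base), upper = (F_c − F_m)/PAR_ci, middle = (F_m − F_g)/PAR_ci and
lower = F_g (1 − tau_floor)/PAR_ci, where ``tau_floor`` is the fraction of
below-base flux not absorbed by the lower stratum (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError, FormatError, InsufficientDataError
from .indices import INDEX_NAMES
from .lidar import TreeSegmentation

STRATA = ("upper", "middle", "lower")

#: long PAR table schema -> wide component names
_COMPONENT_MAP = {
    ("top", "incident"): "ci", ("top", "reflected"): "cr",
    ("middle", "incident"): "mi", ("middle", "reflected"): "mr",
    ("base", "incident"): "gi", ("base", "reflected"): "gr",
}
PAR_CSV_COLUMNS = ["tree_id", "date", "direction_deg", "level",
                   "orientation", "par_value"]


@dataclass
class PARMeasurement:
    """Six-component reading for one tree/date (one direction or averaged)."""

    tree_id: int
    date: str
    ci: float
    cr: float
    mi: float
    mr: float
    gi: float
    gr: float
    direction_deg: Optional[float] = None
    n_directions: int = 1

    def components(self):
        return np.array([self.ci, self.cr, self.mi, self.mr, self.gi, self.gr])


@dataclass
class StratumFPAR:
    tree_id: int
    stratum: str
    fpar: float
    apar: float
    valid: bool = True


@dataclass(frozen=True)
class StratumThresholds:
    """Height cut points separating upper/middle/lower voxel zones."""

    t_upper: float
    t_lower: float

    def __post_init__(self):
        if not self.t_upper > self.t_lower > 0:
            raise DegenerateDataError(
                f"thresholds must satisfy t_upper > t_lower > 0, got "
                f"({self.t_upper}, {self.t_lower})")


#: the as-published 15 m / 7 m labeling zone boundaries
PAPER_THRESHOLDS = StratumThresholds(15.0, 7.0)


def measurements_from_table(table: pd.DataFrame) -> list[PARMeasurement]:
    """Parse the tidy PAR CSV schema into per-direction measurements."""
    missing = [c for c in PAR_CSV_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"PAR table lacks columns: {missing}")
    out = []
    wide = table.pivot_table(index=["tree_id", "date", "direction_deg"],
                             columns=["level", "orientation"],
                             values="par_value", aggfunc="mean")
    for (tree_id, date, direction), row in wide.iterrows():
        kwargs = {}
        for (level, orientation), name in _COMPONENT_MAP.items():
            kwargs[name] = float(row.get((level, orientation), np.nan))
        out.append(PARMeasurement(tree_id=int(tree_id), date=str(date),
                                  direction_deg=float(direction), **kwargs))
    return out


def average_directions(records: Iterable[PARMeasurement]) -> PARMeasurement:
    """Component-wise mean over the available cardinal directions."""
    records = list(records)
    if not records:
        raise InsufficientDataError("no directional records to average")
    keys = {(r.tree_id, r.date) for r in records}
    if len(keys) > 1:
        raise ConfigurationError(f"records mix trees/dates: {sorted(keys)}")
    comp = np.mean([r.components() for r in records], axis=0)
    r0 = records[0]
    return PARMeasurement(tree_id=r0.tree_id, date=r0.date,
                          ci=comp[0], cr=comp[1], mi=comp[2], mr=comp[3],
                          gi=comp[4], gr=comp[5],
                          direction_deg=None, n_directions=len(records))


@dataclass
class FparResult:
    apar: float
    fpar: float
    valid: bool


def compute_apar_fpar(m: PARMeasurement, mode: str = "paper") -> FparResult:
    """Whole-canopy APAR and fPAR for one measurement (see module docs)."""
    if m.ci <= 0:
        raise ConfigurationError(
            f"tree {m.tree_id}: PAR_ci must be > 0, got {m.ci}")
    if mode == "paper":
        apar = m.ci - m.cr - (m.gi - m.gr) - (m.mi - m.mr)
    elif mode == "two_layer":
        apar = (m.ci - m.cr) - (m.gi - m.gr)
    else:
        raise ConfigurationError(f"unknown fPAR mode {mode!r}")
    fpar = apar / m.ci
    return FparResult(apar=apar, fpar=fpar, valid=bool(0.0 <= fpar <= 1.0))


def compute_layer_fpar(m: PARMeasurement,
                       tau_floor: float = 0.0) -> list[StratumFPAR]:
    """Per-stratum fPAR from net-flux differences between sensor levels."""
    if m.ci <= 0:
        raise ConfigurationError(
            f"tree {m.tree_id}: PAR_ci must be > 0, got {m.ci}")
    if not 0.0 <= tau_floor <= 1.0:
        raise ConfigurationError("tau_floor must be in [0, 1]")
    f_c = m.ci - m.cr
    f_m = m.mi - m.mr
    f_g = m.gi - m.gr
    apar = {"upper": f_c - f_m, "middle": f_m - f_g,
            "lower": f_g * (1.0 - tau_floor)}
    out = []
    for stratum in STRATA:
        fpar = apar[stratum] / m.ci
        out.append(StratumFPAR(tree_id=m.tree_id, stratum=stratum,
                               fpar=fpar, apar=apar[stratum],
                               valid=bool(0.0 <= fpar <= 1.0)))
    return out


def layer_fpar_table(par_table: pd.DataFrame,
                     tau_floor: float = 0.0) -> pd.DataFrame:
    """Vectorized direction-averaging + per-stratum fPAR for a PAR table.

    Returns one row per tree x date x stratum: tree_id, date, stratum, fpar,
    apar, n_directions, valid. Records with non-positive averaged PAR_ci are
    dropped with a warning.
    """
    missing = [c for c in PAR_CSV_COLUMNS if c not in par_table.columns]
    if missing:
        raise FormatError(f"PAR table lacks columns: {missing}")
    n_dir = (par_table.groupby(["tree_id", "date"])["direction_deg"]
             .nunique().rename("n_directions"))
    wide = par_table.pivot_table(index=["tree_id", "date"],
                                 columns=["level", "orientation"],
                                 values="par_value", aggfunc="mean")
    comp = {name: wide.get((level, orientation),
                           pd.Series(np.nan, index=wide.index)).to_numpy()
            for (level, orientation), name in _COMPONENT_MAP.items()}
    ci = comp["ci"]
    usable = ci > 0
    if not usable.all():
        warnings.warn(f"dropping {int((~usable).sum())} records with "
                      "non-positive PAR_ci")
    f_c = comp["ci"] - comp["cr"]
    f_m = comp["mi"] - comp["mr"]
    f_g = comp["gi"] - comp["gr"]
    apar = {"upper": f_c - f_m, "middle": f_m - f_g,
            "lower": f_g * (1.0 - tau_floor)}
    idx = wide.index.to_frame(index=False)
    frames = []
    for stratum in STRATA:
        df = idx.copy()
        df["stratum"] = stratum
        df["apar"] = apar[stratum]
        with np.errstate(divide="ignore", invalid="ignore"):
            df["fpar"] = np.where(usable, apar[stratum] / ci, np.nan)
        df["valid"] = (df["fpar"] >= 0) & (df["fpar"] <= 1)
        frames.append(df[usable])
    out = pd.concat(frames, ignore_index=True)
    out = out.merge(n_dir.reset_index(), on=["tree_id", "date"], how="left")
    return out.sort_values(["tree_id", "date", "stratum"], ignore_index=True)


def derive_thresholds(tree_heights, p_upper: float = 75.0,
                      p_lower: float = 40.0) -> StratumThresholds:
    """Stratum cut points as percentiles of the stand's tree heights.

    Linear-interpolation percentiles; the published fixed 15 m / 7 m zones
    correspond approximately to the 75th / 40th percentiles of the stand.
    """
    heights = np.asarray(list(tree_heights), dtype=float)
    if heights.size == 0:
        raise InsufficientDataError("no tree heights supplied")
    if heights.size < 2:
        raise InsufficientDataError("need >= 2 tree heights")
    if not p_upper > p_lower:
        raise ConfigurationError("p_upper must exceed p_lower")
    t_upper = float(np.percentile(heights, p_upper, method="linear"))
    t_lower = float(np.percentile(heights, p_lower, method="linear"))
    if t_upper <= t_lower:
        raise DegenerateDataError(
            f"degenerate stand: percentile thresholds collapse "
            f"({t_upper} <= {t_lower})")
    return StratumThresholds(t_upper, t_lower)


def assign_strata(table: pd.DataFrame,
                  thresholds: StratumThresholds = PAPER_THRESHOLDS,
                  height_column: str = "z") -> pd.DataFrame:
    """Label every voxel upper/middle/lower by its centroid height Z.

    upper: Z >= t_upper; middle: t_lower <= Z < t_upper; lower: Z < t_lower.
    """
    z = table[height_column].to_numpy(dtype=float)
    out = table.copy()
    out["stratum"] = np.select(
        [z >= thresholds.t_upper, z >= thresholds.t_lower],
        ["upper", "middle"], default="lower")
    return out


def label_voxels(table: pd.DataFrame, stratum_fpar: pd.DataFrame,
                 segmentation: TreeSegmentation,
                 predictors: list[str] = INDEX_NAMES,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach tree ids and reference fPAR labels to a stratified voxel table.

    Each voxel inherits the segment label at its column's (x, y); voxels of
    a measured tree receive that tree's fPAR for their stratum; background
    voxels and unmeasured strata stay unlabeled (NaN, with a warning).

    Returns ``(voxel_table, training_table)`` where the training table has
    one row per measured tree x stratum with stratum-mean VI predictors —
    the tree-level unit the regressors are fitted on.
    """
    if "stratum" not in table.columns:
        raise FormatError("voxel table lacks a 'stratum' column; "
                          "run assign_strata first")
    out = table.copy()
    out["tree_id"] = segmentation.label_at(out["x"].to_numpy(),
                                           out["y"].to_numpy())
    ref = stratum_fpar.rename(columns={"fpar": "fpar_label"})
    ref = ref[ref["tree_id"].isin(out.loc[out["tree_id"] > 0, "tree_id"])]
    out = out.merge(ref[["tree_id", "stratum", "fpar_label"]],
                    on=["tree_id", "stratum"], how="left")

    measured = set(stratum_fpar["tree_id"])
    segmented = set(out.loc[out["tree_id"] > 0, "tree_id"])
    missing_pairs = (out.loc[(out["tree_id"] > 0)
                             & out["tree_id"].isin(measured)
                             & out["fpar_label"].isna(),
                             ["tree_id", "stratum"]].drop_duplicates())
    if len(missing_pairs):
        warnings.warn(f"{len(missing_pairs)} tree/stratum pairs lack a "
                      "measured fPAR; left unlabeled")
    if segmented - measured:
        warnings.warn(f"{len(segmented - measured)} segmented trees have no "
                      "PAR measurements; left unlabeled")

    labeled = out[out["fpar_label"].notna()]
    agg = {name: "mean" for name in predictors if name in labeled.columns}
    agg["fpar_label"] = "first"
    training = (labeled.groupby(["tree_id", "stratum"], as_index=False)
                .agg(agg))
    training["n_voxels"] = (labeled.groupby(["tree_id", "stratum"])
                            .size().to_numpy())
    return out, training
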