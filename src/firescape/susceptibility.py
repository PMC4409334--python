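"""Frequency-ratio susceptibility analysis.

For each causative factor the value range is divided into class intervals
and, per class, the frequency ratio

    fr = (fire cells in class / all fire cells)
         / (cells in class / all cells)

is computed over the valid cells of a stratum.  fr > 1 marks a class with
elevated fire propensity.  Per cell, the fire susceptibility index (FSI)
is the sum of the cell's class frequency ratios over all factors, and
dominant causative factors within highly susceptible pixels are ranked by
their mean frequency ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from firescape.errors import (
    ClassificationError,
    ConsistencyError,
    DegenerateStratumError,
)
from firescape.grid import CATEGORICAL, CONTINUOUS, Raster, _require_aligned

NODATA_CLASS = -1


@dataclass(frozen=True)
class FactorDef:
    """One causative factor and its classing rule.

    Continuous factors carry strictly increasing ``breakpoints``; values
    are binned left-closed/right-open with the last interval closed.
    Categorical factors carry the list of admissible ``codes``.
    """

    name: str
    kind: str
    breakpoints: tuple[float, ...] = ()
    codes: tuple[int, ...] = ()
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == CONTINUOUS:
            bp = np.asarray(self.breakpoints, dtype=float)
            if bp.size < 3:
                raise ValueError(f"{self.name}: need >= 2 classes (>= 3 breakpoints)")
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"{self.name}: breakpoints must be strictly increasing")
        elif self.kind == CATEGORICAL:
            if len(self.codes) < 2:
                raise ValueError(f"{self.name}: need >= 2 category codes")
            if len(set(self.codes)) != len(self.codes):
                raise ValueError(f"{self.name}: duplicate codes")
        else:
            raise ValueError(f"{self.name}: kind must be continuous or categorical")

    @property
    def n_classes(self) -> int:
        if self.kind == CONTINUOUS:
            return len(self.breakpoints) - 1
        return len(self.codes)

    def class_labels(self) -> list[str]:
        if self.labels:
            return list(self.labels)
        if self.kind == CONTINUOUS:
            bp = self.breakpoints
            return [_fmt_interval(bp[i], bp[i + 1]) for i in range(len(bp) - 1)]
        return [str(c) for c in self.codes]


def _fmt_interval(lo: float, hi: float) -> str:
    def f(v: float) -> str:
        if np.isinf(v):
            return "inf"
        return f"{v:g}"

    return f"{f(lo)}-{f(hi)}"


@dataclass(frozen=True)
class FactorScheme:
    """Ordered collection of uniquely named factors."""

    factors: tuple[FactorDef, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    def __getitem__(self, name: str) -> FactorDef:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "breakpoints": list(f.breakpoints),
                    "codes": list(f.codes),
                    "labels": list(f.labels),
                }
                for f in self.factors
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FactorScheme":
        raw = json.loads(text)
        return cls(
            tuple(
                FactorDef(
                    name=d["name"],
                    kind=d["kind"],
                    breakpoints=tuple(d.get("breakpoints", ())),
                    codes=tuple(d.get("codes", ())),
                    labels=tuple(d.get("labels", ())),
                )
                for d in raw
            )
        )


def default_factor_scheme(n_landcover_classes: int = 8) -> FactorScheme:
    """Default classing mirroring the class intervals of the source analysis.

    Tree cover 25/51/75/100 %, elevation 0/100/500/2000/+inf m, slope in
    5-degree bins to 90, aspect in eight compass octants, temperature in
    10-degree bins, population density 0/25/50/75/150/300/+inf per km2,
    plus travel-time and distance bins.  All overridable via JSON config.
    """
    inf = float("inf")
    return FactorScheme(
        (
            FactorDef("tree_cover", CONTINUOUS, breakpoints=(25, 51, 75, 100)),
            FactorDef("elevation", CONTINUOUS, breakpoints=(0, 100, 500, 2000, inf)),
            FactorDef("slope", CONTINUOUS, breakpoints=tuple(np.arange(0.0, 95.0, 5.0))),
            FactorDef("aspect", CONTINUOUS, breakpoints=tuple(np.arange(0.0, 405.0, 45.0))),
            FactorDef("temperature", CONTINUOUS, breakpoints=tuple(np.arange(-10.0, 60.0, 10.0))),
            FactorDef(
                "population_density",
                CONTINUOUS,
                breakpoints=(0, 25, 50, 75, 150, 300, inf),
            ),
            FactorDef("travel_time", CONTINUOUS, breakpoints=(0, 1, 2, 3, 5, 10, 24, inf)),
            FactorDef("dist_road", CONTINUOUS, breakpoints=(0, 1, 2, 5, 10, 50, inf)),
            FactorDef("dist_forest_edge", CONTINUOUS, breakpoints=(0, 1, 2, 5, 10, 50, inf)),
            FactorDef("land_cover", CATEGORICAL, codes=tuple(range(n_landcover_classes))),
        )
    )


def classify_factor(values: Raster, factor: FactorDef) -> Raster:
    """Bin a covariate raster into the factor's class codes.

    Continuous values are binned left-closed/right-open with the last
    interval closed at the top; values outside the breakpoints (and
    nodata) map to the nodata class code -1.  Categorical values keep
    their own codes; undeclared codes map to nodata.
    """
    vals = values.values
    out = np.full(vals.shape, NODATA_CLASS, dtype=np.int32)
    if factor.kind == CONTINUOUS:
        v = vals.astype(float)
        finite = np.isfinite(v) & values.valid
        bp = np.asarray(factor.breakpoints, dtype=float)
        # right=False: bp[i] <= v < bp[i+1]; top edge folded into last class
        cls = np.digitize(v, bp, right=False) - 1
        at_top = finite & (v == bp[-1])
        ok = finite & (cls >= 0) & (cls < factor.n_classes)
        out[ok] = cls[ok]
        out[at_top] = factor.n_classes - 1
    else:
        code_ok = np.isin(vals, factor.codes) & values.valid
        out[code_ok] = vals[code_ok].astype(np.int32)
    if not (out != NODATA_CLASS).any():
        raise ClassificationError(f"{factor.name}: no value falls in any class")
    return Raster(values.geometry, out, kind=CATEGORICAL, nodata=NODATA_CLASS, name=factor.name)


def _stratum_valid(
    fire: Raster, class_raster: Raster, stratum_mask: Raster | None
) -> np.ndarray:
    _require_aligned(fire, class_raster, *( [stratum_mask] if stratum_mask is not None else [] ))
    valid = fire.valid & class_raster.valid & (class_raster.values != NODATA_CLASS)
    if stratum_mask is not None:
        valid &= stratum_mask.values == 1
    return valid


def frequency_ratio_table(
    fire: Raster,
    class_raster: Raster,
    stratum_mask: Raster | None = None,
    factor: str = "",
    stratum: str = "all",
) -> pd.DataFrame:
    """Per-class frequency ratios for one classified factor in one stratum.

    Returns a DataFrame with columns ``factor, class_code, class_label,
    n_cells, n_fire_cells, fr, stratum``.  Classes with no cells are
    omitted; a stratum without fire cells is an error.
    """
    valid = _stratum_valid(fire, class_raster, stratum_mask)
    codes = class_raster.values[valid]
    fires = fire.values[valid].astype(bool)
    n_total = int(valid.sum())
    n_fire = int(fires.sum())
    if n_total == 0 or n_fire == 0:
        raise DegenerateStratumError(f"stratum {stratum!r} has no fire cells")
    uniq = np.unique(codes)
    rows = []
    for code in uniq:
        in_class = codes == code
        n_c = int(in_class.sum())
        n_f = int(fires[in_class].sum())
        fr = (n_f / n_fire) / (n_c / n_total)
        rows.append(
            {
                "factor": factor or class_raster.name,
                "class_code": int(code),
                "class_label": str(int(code)),
                "n_cells": n_c,
                "n_fire_cells": n_f,
                "fr": fr,
                "stratum": stratum,
            }
        )
    return pd.DataFrame(rows)


def label_fr_table(table: pd.DataFrame, scheme: FactorScheme) -> pd.DataFrame:
    """Replace numeric class codes with human-readable labels where known."""
    out = table.copy()
    for fname in out["factor"].unique():
        try:
            fdef = scheme[fname]
        except KeyError:
            continue
        labels = fdef.class_labels()
        codes = fdef.codes if fdef.kind == CATEGORICAL else tuple(range(fdef.n_classes))
        lut = {int(c): lab for c, lab in zip(codes, labels)}
        sel = out["factor"] == fname
        out.loc[sel, "class_label"] = out.loc[sel, "class_code"].map(
            lambda c: lut.get(int(c), str(int(c)))
        )
    return out


@dataclass
class SusceptibilityMap:
    """FSI raster plus the per-factor frequency-ratio rasters behind it."""

    fsi: Raster
    factor_fr: dict[str, Raster] = field(default_factory=dict)


def fire_susceptibility_index(
    fr_table: pd.DataFrame,
    class_rasters: Mapping[str, Raster],
) -> SusceptibilityMap:
    """Per-cell FSI = sum over factors of the cell's class frequency ratio.

    Every class observed in a raster must have an FR row; cells where any
    factor is nodata become nodata (complete-case propagation).
    """
    geoms = {r.geometry for r in class_rasters.values()}
    if len(geoms) != 1:
        raise ValueError("class rasters must share one geometry")
    geom = geoms.pop()
    fsi = np.zeros(geom.shape, dtype=float)
    invalid = np.zeros(geom.shape, dtype=bool)
    factor_fr: dict[str, Raster] = {}
    for fname, craster in class_rasters.items():
        sub = fr_table[fr_table["factor"] == fname]
        lut = dict(zip(sub["class_code"].astype(int), sub["fr"].astype(float)))
        codes = craster.values
        fr_vals = np.full(geom.shape, np.nan)
        cell_invalid = codes == NODATA_CLASS
        for code in np.unique(codes[~cell_invalid]):
            if int(code) not in lut:
                raise ConsistencyError(
                    f"factor {fname!r}: class {int(code)} has no frequency-ratio row"
                )
            fr_vals[codes == code] = lut[int(code)]
        invalid |= cell_invalid
        factor_fr[fname] = Raster(geom, fr_vals, kind=CONTINUOUS, name=f"fr_{fname}")
        fsi = fsi + np.where(cell_invalid, 0.0, np.nan_to_num(fr_vals))
    fsi[invalid] = np.nan
    return SusceptibilityMap(
        fsi=Raster(geom, fsi, kind=CONTINUOUS, name="fsi"),
        factor_fr=factor_fr,
    )


@dataclass
class FactorRanking:
    """Factors ordered by mean frequency ratio over selected pixels."""

    ranking: list[tuple[str, float]]
    selection_quantile: float
    n_selected: int
    stratum: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rank": i + 1, "factor": f, "mean_fr": v, "stratum": self.stratum}
                for i, (f, v) in enumerate(self.ranking)
            ]
        )


def rank_factors(
    smap: SusceptibilityMap,
    selection_quantile: float = 0.90,
    stratum_mask: Raster | None = None,
    stratum: str = "all",
) -> FactorRanking:
    """Rank factors by mean FR within high-susceptibility pixels.

    Selects cells with FSI at or above the ``selection_quantile`` quantile
    of FSI within the stratum, averages each factor's per-cell FR over the
    selection, and sorts descending (alphabetical tie-break).
    """
    if not 0 < selection_quantile < 1:
        raise ValueError("selection_quantile must be in (0, 1)")
    valid = smap.fsi.valid
    if stratum_mask is not None:
        valid &= stratum_mask.values == 1
    fsi_vals = smap.fsi.values[valid]
    if fsi_vals.size == 0:
        raise DegenerateStratumError(f"stratum {stratum!r} empty before selection")
    thresh = np.quantile(fsi_vals, selection_quantile)
    selected = valid & (smap.fsi.values >= thresh)
    n_sel = int(selected.sum())
    if n_sel == 0:
        raise DegenerateStratumError("no pixels selected")
    means = {
        fname: float(np.nanmean(fr.values[selected]))
        for fname, fr in smap.factor_fr.items()
    }
    ordered = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return FactorRanking(
        ranking=ordered,
        selection_quantile=selection_quantile,
        n_selected=n_sel,
        stratum=stratum,
    )


def fire_density(fire: Raster, stratum_mask: Raster | None = None) -> float:
    """Fire cells per km2 of stratum area."""
    valid = fire.valid
    if stratum_mask is not None:
        valid &= stratum_mask.values == 1
    n = int(valid.sum())
    if n == 0:
        raise DegenerateStratumError("empty stratum")
    area = n * fire.geometry.cell_size**2
    n_fire = int((fire.values[valid] == 1).sum())
    return n_fire / area
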