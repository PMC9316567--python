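"""Cartesian-plot quantitation of fluorescence transfer.

Pipeline: background estimation from controls, per-cell background
subtraction, normalization so each control population's own-channel median
is 100 normalized fluorescence units (NFU), derivation of classification
bounds from the normalized controls, five-population classification,
Exchange Units (EU), and EU-domain binning.

Exchange Units measure a co-cultured cell's angular position between the
two axes of the normalized green/red plane.  A ray from the origin through
the cell makes an angle theta with the green axis; the diagonal
(green = red, "complete mixing") maps to 0 EU, the green axis to +50 and
the red axis to -50::

    EU = 50 * (45 - theta_degrees) / 45

Cells indistinguishable from a control population are pinned to +/-50 by
their classification, not by their coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    EU_DOMAINS,
    AnalysisConfig,
    BackgroundEstimate,
    ControlBounds,
    Group,
    Role,
    round_half_up,
    subsample,
)
from .segmentation import circularity

log = logging.getLogger("cartplot")

__all__ = [
    "estimate_background",
    "subtract_background",
    "normalize",
    "derive_bounds",
    "classify_cell",
    "exchange_units",
    "bin_eu",
    "flip_orientation",
    "analyze_coculture",
    "CocultureSummary",
]

_GROUP_ORDER = [
    Group.INDIST_RED,
    Group.RED_SOME_GREEN,
    Group.UNCERTAIN,
    Group.GREEN_SOME_RED,
    Group.INDIST_GREEN,
]

_MIRROR = {
    Group.INDIST_RED: Group.INDIST_GREEN,
    Group.INDIST_GREEN: Group.INDIST_RED,
    Group.RED_SOME_GREEN: Group.GREEN_SOME_RED,
    Group.GREEN_SOME_RED: Group.RED_SOME_GREEN,
    Group.UNCERTAIN: Group.UNCERTAIN,
    Group.UNCLASSIFIED: Group.UNCLASSIFIED,
}


def estimate_background(
    control_green: pd.DataFrame,
    control_red: pd.DataFrame,
    mode: str = "cross",
) -> BackgroundEstimate:
    """Background fluorescence per unit area from summated control cells.

    In the default cross-channel mode the red background rate is total red
    fluorescence over total area of the *green*-labelled controls (their red
    signal is background plus bleed-through, never label), and symmetrically
    for green.  ``mode='none'`` returns zero rates.
    """
    if mode == "none":
        return BackgroundEstimate(0.0, 0.0)
    if mode != "cross":
        raise ValueError(f"unknown background mode {mode!r}")
    if len(control_green) == 0 or len(control_red) == 0:
        raise ValueError("both control populations are required to estimate background")
    area_g = float(control_green["area"].sum())
    area_r = float(control_red["area"].sum())
    if area_g <= 0 or area_r <= 0:
        raise ValueError("control cells have zero total area")
    red_bg = float(control_green["red_raw"].sum()) / area_g
    green_bg = float(control_red["green_raw"].sum()) / area_r
    return BackgroundEstimate(green_bg_rate=green_bg, red_bg_rate=red_bg)


def subtract_background(
    green_raw: np.ndarray | float,
    red_raw: np.ndarray | float,
    area: np.ndarray | float,
    bg: BackgroundEstimate,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Area-proportional background subtraction, clamped at zero.

    corrected_c = max(0, raw_c - area * bg_rate_c); negative corrected
    values are clamped because both the log plots and the angular EU
    mapping require non-negative coordinates.
    """
    g = np.maximum(0.0, np.asarray(green_raw, dtype=float) - np.asarray(area, dtype=float) * bg.green_bg_rate)
    r = np.maximum(0.0, np.asarray(red_raw, dtype=float) - np.asarray(area, dtype=float) * bg.red_bg_rate)
    if np.isscalar(green_raw) or np.ndim(green_raw) == 0:
        return float(g), float(r)
    return g, r


def normalize(
    cells: pd.DataFrame,
    control_green: pd.DataFrame,
    control_red: pd.DataFrame,
    bg: BackgroundEstimate,
) -> tuple[pd.DataFrame, float, float]:
    """Express fluorescence in NFU: control own-channel median = 100.

    Background is subtracted from every table first; the green normalization
    median is the median corrected green fluorescence of the green controls
    (symmetric for red).  Returns the combined normalized frame (controls
    and co-cultured cells alike, with ``green_norm``/``red_norm`` columns)
    and the two medians on the corrected-raw scale.
    """
    parts = []
    for df in (control_green, control_red, cells):
        out = df.copy()
        g, r = subtract_background(
            out["green_raw"].to_numpy(), out["red_raw"].to_numpy(), out["area"].to_numpy(), bg
        )
        out["green_corr"] = g
        out["red_corr"] = r
        parts.append(out)
    cg, cr, cc = parts
    median_green = float(np.median(cg["green_corr"]))
    median_red = float(np.median(cr["red_corr"]))
    if median_green <= 0 or median_red <= 0:
        raise ValueError(
            f"control own-channel median must be positive after background "
            f"subtraction (green={median_green:.4g}, red={median_red:.4g})"
        )
    combined = pd.concat([cg, cr, cc], ignore_index=True)
    combined["green_norm"] = 100.0 * combined["green_corr"] / median_green
    combined["red_norm"] = 100.0 * combined["red_corr"] / median_red
    combined = combined.drop(columns=["green_corr", "red_corr"])
    return combined, median_green, median_red


def _trimmed_extrema(values: np.ndarray, trim: float) -> tuple[float, float]:
    """(min, max) after dropping floor(trim * n) order statistics per tail."""
    v = np.sort(np.asarray(values, dtype=float))
    k = int(math.floor(trim * len(v)))
    if 2 * k >= len(v):
        raise ValueError(f"trim={trim} leaves no cells out of {len(v)}")
    return float(v[k]), float(v[len(v) - 1 - k])


def derive_bounds(
    norm_control_green: pd.DataFrame,
    norm_control_red: pd.DataFrame,
    trim: float = 0.0,
) -> ControlBounds:
    """Classification bounds from the normalized control populations.

    ``green_lo`` / ``red_bleed_hi`` are the trimmed minimum green NFU and
    trimmed maximum red NFU among green controls (symmetric for red
    controls).  ``trim`` is the fraction of extreme cells dropped per tail
    (0 = plain min/max).  Raises if the bleed-through ceiling of one
    population reaches the own-channel floor of the other: overlapping
    controls make the five regions ill-defined.
    """
    green_lo, _ = _trimmed_extrema(norm_control_green["green_norm"].to_numpy(), trim)
    _, red_bleed_hi = _trimmed_extrema(norm_control_green["red_norm"].to_numpy(), trim)
    red_lo, _ = _trimmed_extrema(norm_control_red["red_norm"].to_numpy(), trim)
    _, green_bleed_hi = _trimmed_extrema(norm_control_red["green_norm"].to_numpy(), trim)
    return ControlBounds(
        green_lo=green_lo,
        red_bleed_hi=red_bleed_hi,
        red_lo=red_lo,
        green_bleed_hi=green_bleed_hi,
        trim=trim,
    )


def classify_cell(green_norm: float, red_norm: float, bounds: ControlBounds) -> Group:
    """Assign a co-cultured cell to one of the five populations.

    Boundaries are closed toward the indistinguishable labels (conservative
    toward no transfer), and the uncertain region takes precedence where a
    cell lies within both own-channel ranges.
    """
    g, r = green_norm, red_norm
    in_green = g >= bounds.green_lo
    in_red = r >= bounds.red_lo
    if in_green and in_red:
        return Group.UNCERTAIN
    if in_green:
        return Group.INDIST_GREEN if r <= bounds.red_bleed_hi else Group.GREEN_SOME_RED
    if in_red:
        return Group.INDIST_RED if g <= bounds.green_bleed_hi else Group.RED_SOME_GREEN
    return Group.UNCLASSIFIED


def exchange_units(green_norm: float, red_norm: float, group: Group) -> float:
    """Exchange Units of a classified cell.

    Indistinguishable cells are pinned to +/-50.  Otherwise EU is linear in
    the angle theta (degrees) of the cell's origin ray above the green
    axis: EU = 50 * (45 - theta) / 45, so the green axis scores 50, the
    diagonal 0, and the red axis -50.  A cell at the origin with an
    unpinned group has no defined angle and returns NaN.
    """
    if group is Group.UNCLASSIFIED:
        raise ValueError("EU is undefined for unclassified cells")
    if group is Group.INDIST_GREEN:
        return 50.0
    if group is Group.INDIST_RED:
        return -50.0
    if green_norm == 0.0 and red_norm == 0.0:
        return float("nan")
    theta = math.degrees(math.atan2(red_norm, green_norm))
    return 50.0 * (45.0 - theta) / 45.0


def bin_eu(eu: float, group: Group) -> str:
    """Map a classified cell to one of the seven EU domains.

    The +/-50 singleton domains contain exactly the indistinguishable
    groups; other cells fall into five half-open interior intervals, with
    the top interval open above (30 < EU < 50) so that a non-indistinguishable
    cell sitting exactly on an axis stays out of the singletons.
    """
    if group is Group.INDIST_RED:
        return EU_DOMAINS[0]
    if group is Group.INDIST_GREEN:
        return EU_DOMAINS[6]
    if math.isnan(eu):
        raise ValueError("cannot bin undefined EU")
    if eu <= -30.0:
        return EU_DOMAINS[1]
    if eu <= -10.0:
        return EU_DOMAINS[2]
    if eu <= 10.0:
        return EU_DOMAINS[3]
    if eu <= 30.0:
        return EU_DOMAINS[4]
    return EU_DOMAINS[5]


def flip_orientation(classified: pd.DataFrame) -> pd.DataFrame:
    """Mirror the label orientation: EU negated, groups and domains swapped.

    Used when the dye orientation of an experiment is opposite to the rest
    (donor labelled green instead of red), so that results can be compared
    in a common order.  An involution: flipping twice is the identity.
    """
    out = classified.copy()
    out["eu"] = -out["eu"]
    out["group"] = out["group"].map(lambda s: _MIRROR[Group(s)].value if pd.notna(s) else s)
    domain_mirror = dict(zip(EU_DOMAINS, EU_DOMAINS[::-1]))
    out["eu_domain"] = out["eu_domain"].map(lambda d: domain_mirror.get(d, d))
    return out


@dataclass
class CocultureSummary:
    """Per-run summary: counts, percentages, and medians per group/EU domain.

    Percentages are computed against the total number of co-cultured cells
    and rounded half-away-from-zero to one decimal.
    """

    n_cocultured: int
    n_control_green: int
    n_control_red: int
    group_counts: dict[str, int]
    group_pct: dict[str, float]
    domain_counts: dict[str, int]
    domain_pct: dict[str, float]
    group_medians: pd.DataFrame
    domain_medians: pd.DataFrame
    control_medians: pd.DataFrame
    background: BackgroundEstimate = None
    norm_median_green: float = float("nan")
    norm_median_red: float = float("nan")
    bounds: ControlBounds = None

    def to_frame(self) -> pd.DataFrame:
        """One row per group and per EU domain with count and percentage."""
        rows = []
        for name, cnt in self.group_counts.items():
            rows.append({"kind": "group", "label": name, "count": cnt,
                         "pct": self.group_pct[name]})
        for name, cnt in self.domain_counts.items():
            rows.append({"kind": "eu_domain", "label": name, "count": cnt,
                         "pct": self.domain_pct[name]})
        return pd.DataFrame(rows)


def _median_block(df: pd.DataFrame, by: str, order: list[str]) -> pd.DataFrame:
    cols = [c for c in ("circularity", "area", "cnf_norm") if c in df.columns]
    med = df.groupby(by)[cols].median()
    present = [o for o in order if o in med.index]
    return med.loc[present]


def analyze_coculture(
    cocultured: pd.DataFrame,
    control_green: pd.DataFrame,
    control_red: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, CocultureSummary]:
    """Run the full Cartesian-plot pipeline for one experiment.

    Background estimation, normalization, bound derivation, classification,
    EU, EU-domain binning and circularity, applied to the co-cultured cells
    of a single experiment together with its two control populations.
    Inputs larger than the sampling caps are subsampled uniformly under the
    configured seed.  Returns the classified table (controls included, with
    classification columns only on co-cultured rows) and a
    :class:`CocultureSummary`.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    control_green = subsample(control_green.reset_index(drop=True), config.max_controls, rng)
    control_red = subsample(control_red.reset_index(drop=True), config.max_controls, rng)
    cocultured = subsample(cocultured.reset_index(drop=True), config.max_cocultured, rng)

    bg = estimate_background(control_green, control_red, mode=config.background_mode)
    combined, med_g, med_r = normalize(cocultured, control_green, control_red, bg)
    combined["circularity"] = circularity(
        combined["area"].to_numpy(), combined["perimeter"].to_numpy()
    )
    is_cg = combined["role"] == Role.CONTROL_GREEN.value
    is_cr = combined["role"] == Role.CONTROL_RED.value
    is_cc = combined["role"] == Role.COCULTURED.value
    bounds = derive_bounds(combined[is_cg], combined[is_cr], trim=config.trim)
    log.info(
        "analysis constants: bg=(green %.6g, red %.6g)/area, norm medians=(green %.6g, "
        "red %.6g), bounds=(green_lo %.4g, red_bleed_hi %.4g, red_lo %.4g, green_bleed_hi %.4g)",
        bg.green_bg_rate, bg.red_bg_rate, med_g, med_r,
        bounds.green_lo, bounds.red_bleed_hi, bounds.red_lo, bounds.green_bleed_hi,
    )

    groups, eus, domains = [], [], []
    for g, r in zip(combined.loc[is_cc, "green_norm"], combined.loc[is_cc, "red_norm"]):
        grp = classify_cell(g, r, bounds)
        groups.append(grp.value)
        if grp is Group.UNCLASSIFIED:
            eus.append(float("nan"))
            domains.append(None)
        else:
            eu = exchange_units(g, r, grp)
            eus.append(eu)
            domains.append(bin_eu(eu, grp) if not math.isnan(eu) else None)
    combined["group"] = None
    combined["eu"] = float("nan")
    combined["eu_domain"] = None
    combined.loc[is_cc, "group"] = groups
    combined.loc[is_cc, "eu"] = eus
    combined.loc[is_cc, "eu_domain"] = domains
    if config.flip_eu:
        cc_part = flip_orientation(combined[is_cc])
        combined.loc[is_cc, ["group", "eu", "eu_domain"]] = cc_part[
            ["group", "eu", "eu_domain"]
        ].to_numpy()

    cc = combined[is_cc]
    n_cc = int(is_cc.sum())
    n_uncl = int((cc["group"] == Group.UNCLASSIFIED.value).sum())
    if n_uncl:
        log.warning(
            "%d of %d co-cultured cells fall below both control lower bounds "
            "and are UNCLASSIFIED (excluded from five-group percentages)", n_uncl, n_cc
        )
    group_counts = {g.value: int((cc["group"] == g.value).sum())
                    for g in _GROUP_ORDER + [Group.UNCLASSIFIED]}
    domain_counts = {d: int((cc["eu_domain"] == d).sum()) for d in EU_DOMAINS}
    pct = lambda n: round_half_up(100.0 * n / n_cc, 1) if n_cc else 0.0
    summary = CocultureSummary(
        n_cocultured=n_cc,
        n_control_green=int(is_cg.sum()),
        n_control_red=int(is_cr.sum()),
        group_counts=group_counts,
        group_pct={k: pct(v) for k, v in group_counts.items()},
        domain_counts=domain_counts,
        domain_pct={k: pct(v) for k, v in domain_counts.items()},
        group_medians=_median_block(cc.dropna(subset=["group"]), "group",
                                    [g.value for g in _GROUP_ORDER + [Group.UNCLASSIFIED]]),
        domain_medians=_median_block(cc.dropna(subset=["eu_domain"]), "eu_domain",
                                     list(EU_DOMAINS)),
        control_medians=pd.concat([
            combined[is_cg][["green_norm", "red_norm", "circularity", "area"]].median().rename("control_green"),
            combined[is_cr][["green_norm", "red_norm", "circularity", "area"]].median().rename("control_red"),
        ], axis=1).T,
        background=bg,
        norm_median_green=med_g,
        norm_median_red=med_r,
        bounds=bounds,
    )
    return combined, summary
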