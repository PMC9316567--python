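"""Corrected nuclear fluorescence (cnf) and its normalization.

Nuclear anti-5mc fluorescence is corrected for DNA content by dividing by
the propidium-iodide fluorescence of the same nucleus (cnf = 5mc / PI);
cnf is then normalized so the median of the control fibroblast (red)
population is 100:

    normalized cnf = 100 * cnf / median(cnf of control red cells)

The fibroblast controls serve as the stable standard against which every
other cell in the experiment is expressed, allowing comparison across
experiments.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import EU_DOMAINS, Group, Role

log = logging.getLogger("cartplot")

__all__ = ["cnf", "normalize_cnf", "add_methylation", "methylation_summary"]


def cnf(f5mc: np.ndarray | float, fpi: np.ndarray | float) -> np.ndarray | float:
    """cnf = f5mc / fpi; requires positive PI fluorescence.

    The ratio cancels DNA content (cell-cycle stage, aneuploidy), so
    doubling both nuclear signals leaves cnf unchanged.
    """
    f = np.asarray(f5mc, dtype=float)
    p = np.asarray(fpi, dtype=float)
    if np.any(~(p > 0) & ~np.isnan(p)):
        raise ValueError("fpi must be positive wherever present")
    out = f / p
    if np.isscalar(f5mc) or np.ndim(f5mc) == 0:
        return float(out)
    return out


def normalize_cnf(
    cnf_values: np.ndarray,
    control_red_cnf: np.ndarray,
    mad_k: float | None = None,
) -> tuple[np.ndarray, float]:
    """Scale cnf so the control fibroblast median is 100.

    ``mad_k`` optionally excludes control cells more than ``k`` median
    absolute deviations from the control median before that median is
    taken (off by default; the median itself is already robust).  Returns
    the normalized values and the control median used.
    """
    ctrl = np.asarray(control_red_cnf, dtype=float)
    ctrl = ctrl[~np.isnan(ctrl)]
    if ctrl.size == 0:
        raise ValueError("no control fibroblast cnf values to normalize against")
    if mad_k is not None:
        med = np.median(ctrl)
        mad = np.median(np.abs(ctrl - med))
        if mad > 0:
            keep = np.abs(ctrl - med) <= mad_k * mad
            n_out = int((~keep).sum())
            if n_out:
                log.info("cnf normalization: excluded %d control outlier(s) (|cnf-med| > %g MAD)",
                         n_out, mad_k)
            ctrl = ctrl[keep]
    median = float(np.median(ctrl))
    if median <= 0:
        raise ValueError(f"control cnf median must be positive, got {median}")
    return 100.0 * np.asarray(cnf_values, dtype=float) / median, median


def add_methylation(
    classified: pd.DataFrame, mad_k: float | None = None
) -> pd.DataFrame:
    """Attach ``cnf`` and ``cnf_norm`` columns to a classified table.

    Rows lacking 5mc/PI keep NaN; rows with non-positive PI are flagged by
    exclusion (NaN) and logged.  Normalization uses the control red
    (fibroblast) rows of the same table.
    """
    out = classified.copy()
    f = out["f5mc"].to_numpy(dtype=float)
    p = out["fpi"].to_numpy(dtype=float)
    bad = ~np.isnan(f) & ~(p > 0)
    if bad.any():
        log.warning("%d cell(s) with f5mc but non-positive fpi excluded from cnf", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(p > 0, f / p, np.nan)
    out["cnf"] = c
    ctrl = out.loc[out["role"] == Role.CONTROL_RED.value, "cnf"].to_numpy()
    out["cnf_norm"], _ = normalize_cnf(out["cnf"].to_numpy(), ctrl, mad_k=mad_k)
    return out


def methylation_summary(classified: pd.DataFrame) -> dict[str, pd.Series]:
    """Median normalized cnf per Cartesian group, per EU domain, and for controls.

    Empty groups/domains are absent from the result, not reported as zero.
    """
    cc = classified[classified["role"] == Role.COCULTURED.value]
    by_group = cc.dropna(subset=["group", "cnf_norm"]).groupby("group")["cnf_norm"].median()
    order = [g.value for g in Group if g.value in by_group.index]
    by_domain = cc.dropna(subset=["eu_domain", "cnf_norm"]).groupby("eu_domain")["cnf_norm"].median()
    dorder = [d for d in EU_DOMAINS if d in by_domain.index]
    controls = classified.groupby("role")["cnf_norm"].median()
    return {
        "by_group": by_group.loc[order],
        "by_eu_domain": by_domain.loc[dorder],
        "controls": controls,
    }
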