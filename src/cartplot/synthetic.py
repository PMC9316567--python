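"""Synthetic co-culture data with known ground truth.

Generates per-cell measurement tables for isolated control populations and
for a co-culture, with every downstream quantity (transfer status, received
amount, morphology coupling, methylation structure) known exactly, plus an
optional renderer that paints the cells into a two-channel image with a
matching label mask.

The generator emulates the salient statistics of fixed co-culture
monolayers:

* own-channel integrated fluorescence is log-normal — control populations
  show a wide, skewed spread best viewed on log axes;
* the opposite channel of a control cell carries only additive background
  (proportional to area) plus a small bleed-through term;
* transfer is predominantly donor (red fibroblast) to acceptor (green
  cancer cell): a transferring acceptor receives a Beta-distributed
  fraction of a donor-level fluorescence draw — right-skewed, so most
  recipients gain little label and a few gain much;
* morphology couples to uptake (cell-profile area up, circularity down,
  linearly in the received fraction);
* corrected nuclear fluorescence (cnf = 5mc/PI) is log-normal per
  population with fibroblasts above cancer cells, and co-culture shifts
  the fibroblast level down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Role

__all__ = ["SyntheticConfig", "generate_controls", "generate_coculture", "render_images"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic co-culture model (defaults = study conditions).

    Fluorescence is in arbitrary integrated units, lengths in pixels.
    ``green`` is the cancer-cell population, ``red`` the fibroblast
    population (the predominant donor).
    """

    n_control_green: int = 100
    n_control_red: int = 100
    n_cocultured: int = 1000

    # own-channel integrated fluorescence: lognormal(log-mean, log-sd)
    green_signal_mu: float = 9.2
    green_signal_sigma: float = 0.6
    red_signal_mu: float = 9.8
    red_signal_sigma: float = 0.6

    #: opposite-channel bleed-through, as a fraction of an own-level draw
    bleed_level: float = 0.01
    #: additive background per unit area, per channel
    bg_green_rate: float = 0.5
    bg_red_rate: float = 0.5

    #: probability an acceptor (green) cell receives donor label
    transfer_fraction: float = 0.7
    #: Beta(a, b) for the received fraction of a donor-level draw
    transfer_amount_a: float = 0.6
    transfer_amount_b: float = 2.4
    #: pin the received fraction to a constant instead of a Beta draw
    transfer_amount_const: float | None = None
    #: probability a donor (red) cell receives acceptor label (reverse transfer)
    reverse_transfer_fraction: float = 0.05
    #: fraction of co-cultured cells that are donors (red fibroblasts)
    donor_mix: float = 0.5

    # morphology: lognormal areas (px^2), Beta circularities per population
    green_area_mu: float = math.log(1200.0)
    green_area_sigma: float = 0.35
    red_area_mu: float = math.log(2500.0)
    red_area_sigma: float = 0.40
    green_circ_a: float = 14.0
    green_circ_b: float = 4.0
    red_circ_a: float = 5.0
    red_circ_b: float = 6.0
    #: linear coupling of morphology to the received fraction
    area_coupling: float = 0.8
    circ_coupling: float = 0.45

    # methylation: lognormal cnf per population; PI (DNA content) lognormal
    green_cnf_mu: float = math.log(0.30)
    green_cnf_sigma: float = 0.25
    red_cnf_mu: float = math.log(0.50)
    red_cnf_sigma: float = 0.25
    #: multiplicative cnf shift of the red population in co-culture
    coculture_cnf_shift: float = -0.4
    fpi_mu: float = math.log(1.0e4)
    fpi_sigma: float = 0.2

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control_green, self.n_control_red, self.n_cocultured) <= 0:
            raise ValueError("all cell counts must be positive")
        for name in ("transfer_fraction", "reverse_transfer_fraction", "donor_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bleed_level < 0 or self.bg_green_rate < 0 or self.bg_red_rate < 0:
            raise ValueError("bleed and background rates must be non-negative")
        if self.coculture_cnf_shift <= -1.0:
            raise ValueError("coculture_cnf_shift must exceed -1 (cnf stays positive)")


def _morphology(cfg: SyntheticConfig, pop: str, n: int, rng: np.random.Generator,
                received: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(area, perimeter, circularity); coupling shifts area up, circularity down."""
    if pop == "green":
        area = rng.lognormal(cfg.green_area_mu, cfg.green_area_sigma, n)
        circ = rng.beta(cfg.green_circ_a, cfg.green_circ_b, n)
    else:
        area = rng.lognormal(cfg.red_area_mu, cfg.red_area_sigma, n)
        circ = rng.beta(cfg.red_circ_a, cfg.red_circ_b, n)
    circ = np.clip(circ, 0.05, 1.0)
    if received is not None:
        area = area * (1.0 + cfg.area_coupling * received)
        circ = np.clip(circ * (1.0 - cfg.circ_coupling * received), 0.05, 1.0)
    # perimeter consistent with the shape factor: P = sqrt(4*pi*A/c)
    perim = np.sqrt(4.0 * math.pi * area / circ)
    return area, perim, circ


def _cnf_fields(cfg: SyntheticConfig, pop: str, n: int, rng: np.random.Generator,
                cocultured: bool) -> tuple[np.ndarray, np.ndarray]:
    """(f5mc, fpi) so that f5mc/fpi follows the population cnf distribution."""
    if pop == "green":
        cnf = rng.lognormal(cfg.green_cnf_mu, cfg.green_cnf_sigma, n)
    else:
        cnf = rng.lognormal(cfg.red_cnf_mu, cfg.red_cnf_sigma, n)
        if cocultured:
            cnf = cnf * (1.0 + cfg.coculture_cnf_shift)
    fpi = rng.lognormal(cfg.fpi_mu, cfg.fpi_sigma, n)
    return cnf * fpi, fpi


def _bleed(cfg: SyntheticConfig, opposite: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.bleed_level == 0.0:
        return np.zeros(n)
    if opposite == "green":
        return cfg.bleed_level * rng.lognormal(cfg.green_signal_mu, cfg.green_signal_sigma, n)
    return cfg.bleed_level * rng.lognormal(cfg.red_signal_mu, cfg.red_signal_sigma, n)


def _table(cfg: SyntheticConfig, prefix: str, experiment_id: str, role: Role, n: int,
           green_raw: np.ndarray, red_raw: np.ndarray,
           area: np.ndarray, perim: np.ndarray,
           f5mc: np.ndarray, fpi: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [f"{prefix}_{i}" for i in range(n)],
        "experiment_id": experiment_id,
        "role": role.value,
        "green_raw": green_raw,
        "red_raw": red_raw,
        "area": area,
        "perimeter": perim,
        "f5mc": f5mc,
        "fpi": fpi,
    })


def generate_controls(
    cfg: SyntheticConfig, experiment_id: str = "sim"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isolated control populations (green cancer cells, red fibroblasts).

    Own-channel fluorescence is a log-normal draw; the opposite channel is
    area-proportional background plus bleed-through only.  Deterministic
    under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    for pop, role, n in (
        ("green", Role.CONTROL_GREEN, cfg.n_control_green),
        ("red", Role.CONTROL_RED, cfg.n_control_red),
    ):
        area, perim, _ = _morphology(cfg, pop, n, rng)
        if pop == "green":
            own = rng.lognormal(cfg.green_signal_mu, cfg.green_signal_sigma, n)
            green = own + cfg.bg_green_rate * area
            red = _bleed(cfg, "red", n, rng) + cfg.bg_red_rate * area
        else:
            own = rng.lognormal(cfg.red_signal_mu, cfg.red_signal_sigma, n)
            red = own + cfg.bg_red_rate * area
            green = _bleed(cfg, "green", n, rng) + cfg.bg_green_rate * area
        f5mc, fpi = _cnf_fields(cfg, pop, n, rng, cocultured=False)
        out.append(_table(cfg, f"ctrl_{pop}", experiment_id, role, n,
                          green, red, area, perim, f5mc, fpi))
    return out[0], out[1]


def generate_coculture(
    cfg: SyntheticConfig, experiment_id: str = "sim"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Co-cultured cells plus their ground truth.

    A ``donor_mix`` fraction of cells are donors (red fibroblasts), the rest
    acceptors (green cancer cells).  With probability ``transfer_fraction``
    an acceptor receives ``amount`` (a Beta draw) times a donor-level
    red-fluorescence draw; donors receive green label symmetrically with
    the (small) reverse probability.  Morphology and cnf are shifted per
    the coupling and methylation models.

    Returns ``(cells, truth)`` where ``truth`` has one row per cell:
    ``cell_id``, ``is_donor``, ``true_amount`` (received fraction, 0 if
    none) and ``true_received`` (received raw fluorescence in the acquired
    channel).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_cocultured
    is_donor = rng.random(n) < cfg.donor_mix
    amount = np.zeros(n)
    received = np.zeros(n)

    def _amount(k: int) -> np.ndarray:
        if cfg.transfer_amount_const is not None:
            return np.full(k, cfg.transfer_amount_const)
        return rng.beta(cfg.transfer_amount_a, cfg.transfer_amount_b, k)

    transfers = (~is_donor) & (rng.random(n) < cfg.transfer_fraction)
    k = int(transfers.sum())
    amount[transfers] = _amount(k)
    received[transfers] = amount[transfers] * rng.lognormal(
        cfg.red_signal_mu, cfg.red_signal_sigma, k)

    rev = is_donor & (rng.random(n) < cfg.reverse_transfer_fraction)
    kr = int(rev.sum())
    amount[rev] = _amount(kr)
    received[rev] = amount[rev] * rng.lognormal(
        cfg.green_signal_mu, cfg.green_signal_sigma, kr)

    green = np.empty(n)
    red = np.empty(n)
    area = np.empty(n)
    perim = np.empty(n)
    f5mc = np.empty(n)
    fpi = np.empty(n)

    for donor in (False, True):
        sel = is_donor == donor
        m = int(sel.sum())
        if m == 0:
            continue
        pop = "red" if donor else "green"
        a, p, _ = _morphology(cfg, pop, m, rng, received=amount[sel])
        area[sel], perim[sel] = a, p
        own = rng.lognormal(
            cfg.red_signal_mu if donor else cfg.green_signal_mu,
            cfg.red_signal_sigma if donor else cfg.green_signal_sigma, m)
        bleed = _bleed(cfg, "green" if donor else "red", m, rng)
        if donor:
            red[sel] = own + cfg.bg_red_rate * a
            green[sel] = bleed + received[sel] + cfg.bg_green_rate * a
        else:
            green[sel] = own + cfg.bg_green_rate * a
            red[sel] = bleed + received[sel] + cfg.bg_red_rate * a
        mc, pi = _cnf_fields(cfg, pop, m, rng, cocultured=True)
        f5mc[sel], fpi[sel] = mc, pi

    cells = _table(cfg, "cc", experiment_id, Role.COCULTURED, n,
                   green, red, area, perim, f5mc, fpi)
    truth = pd.DataFrame({
        "cell_id": cells["cell_id"],
        "is_donor": is_donor,
        "true_amount": amount,
        "true_received": received,
    })
    return cells, truth


def render_images(
    cells: pd.DataFrame,
    *,
    canvas: tuple[int, int] = (1024, 1024),
    margin: int = 4,
    punctate: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint cells as elliptical blobs into a two-channel image.

    Each cell becomes an axis-aligned ellipse whose pixel area matches its
    ``area`` and whose aspect ratio is derived from its circularity; the
    per-channel intensity over the blob sums exactly to the cell's raw
    fluorescence (a ``punctate`` fraction of it is re-distributed as random
    puncta to mimic organelle-concentrated label).  Cells are placed on a
    non-overlapping grid; a canvas too small for all cells raises.

    Returns ``(image, label_mask)`` with ``image`` shaped (2, H, W) in
    channel order (green, red) and ``label_mask`` holding cell ``k`` at
    value ``k`` in row order of ``cells`` (1-based).
    """
    from skimage.draw import ellipse as draw_ellipse

    rng = np.random.default_rng(seed)
    h, w = canvas
    image = np.zeros((2, h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.int32)
    if len(cells) == 0:
        return image, mask

    # ellipse semi-axes from area and circularity: pi*a*b = A, with the
    # aspect ratio q = b/a shrinking as circularity drops (q=1 at c=1)
    areas = cells["area"].to_numpy(dtype=float)
    circ = 4.0 * math.pi * areas / cells["perimeter"].to_numpy(dtype=float) ** 2
    q = np.clip(circ, 0.05, 1.0) ** 1.8
    a_ax = np.sqrt(areas / (math.pi * q))
    b_ax = a_ax * q

    cell_w = 2 * a_ax.max() + margin
    cell_h = 2 * b_ax.max() + margin
    ncol = int(w // cell_w)
    nrow = int(h // cell_h)
    if ncol * nrow < len(cells):
        raise ValueError(
            f"canvas {canvas} holds {ncol * nrow} blobs of this size; "
            f"{len(cells)} requested")

    for i, (_, row) in enumerate(cells.iterrows()):
        cy = int((i // ncol) * cell_h + cell_h / 2)
        cx = int((i % ncol) * cell_w + cell_w / 2)
        rr, cc = draw_ellipse(cy, cx, b_ax[i], a_ax[i], shape=(h, w))
        if rr.size == 0:
            raise ValueError(f"cell {row['cell_id']} rendered with zero pixels")
        mask[rr, cc] = i + 1
        npx = rr.size
        for ch, col in ((0, "green_raw"), (1, "red_raw")):
            total = float(row[col])
            base = total * (1.0 - punctate) / npx
            image[ch, rr, cc] += base
            # puncta: concentrate the remainder on random member pixels
            k = max(1, npx // 20)
            pick = rng.choice(npx, size=k, replace=False)
            image[ch, rr[pick], cc[pick]] += total * punctate / k
    return image, mask


def write_images(image: np.ndarray, mask: np.ndarray, directory, prefix: str = "sim") -> None:
    """Write the rendered channels and label mask as TIFF files."""
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{prefix}_image.tif", image.astype(np.float32))
    tifffile.imwrite(directory / f"{prefix}_mask.tif", mask)
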