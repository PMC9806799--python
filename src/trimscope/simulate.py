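"""Ground-truth population sampling and image rendering.

The population model: SLO permeabilizes each cell with a Hill-curve
probability in dose, modulated by a lognormal per-cell membrane-cholesterol
factor; permeabilized cells receive a lognormal antibody amount A and reseal
except for a small failure fraction ("died" cells); TRIM21 (T) and the target
protein (X0) are lognormal; in the targeting condition the remaining target
after ``incubation_h`` hours follows first-order decay saturating in both A
and T with an optional degradation-resistant pool:

    X = X0 * [f_res + (1 - f_res) * exp(-k_i * t)],
    k_i = k_max * A/(A+K_A) * T/(T+K_T).

Downstream phospho channels track the remaining target as beta * X**gamma
with lognormal noise. Rendering draws each cell as a filled nuclear ellipse
plus a nearest-center-clipped cytoplasmic shell, then applies per-round stage
drift, bleaching carryover, background, shot and read noise.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import ellipse as draw_ellipse
from skimage.segmentation import expand_labels

from .config import SimConfig
from .imageset import ImageSet

__all__ = [
    "sample_population",
    "apply_spatial_mode",
    "render_rounds",
    "simulate_field",
    "calibrate_knockdown",
    "calibrate_permeabilization",
    "expected_bulk_knockdown",
    "knockdown_ceiling",
]

# Distinct RNG streams per stage so that, e.g., adding a round never perturbs
# the sampled population.
_STREAM_POPULATION = 1
_STREAM_SPATIAL = 2
_STREAM_RENDER = 3
_CALIBRATION_SEED = 20_240_001  # fixed: calibration is part of the preset definition


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


def _grid_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid cell centers guaranteeing the minimum spacing.

    Cells sit on a regular grid with uniform jitter small enough that even
    worst-case neighbors stay ``min_spacing_px`` apart.
    """
    n = config.n_cells
    h, w = config.field_shape
    m = config.margin_px
    avail_r, avail_c = h - 2 * m, w - 2 * m
    if n == 0:
        return np.zeros((0, 2))
    side = int(math.ceil(math.sqrt(n)))
    pitch_r, pitch_c = avail_r / side, avail_c / side
    pitch = min(pitch_r, pitch_c)
    if pitch < config.min_spacing_px:
        raise ValueError(
            f"field {config.field_shape} too small for {n} cells at minimum "
            f"spacing {config.min_spacing_px} px (grid pitch {pitch:.1f} px)"
        )
    jitter = (pitch - config.min_spacing_px) / 2.0
    idx = rng.choice(side * side, size=n, replace=False)
    gr, gc = np.divmod(idx, side)
    rows = m + (gr + 0.5) * pitch_r + rng.uniform(-jitter, jitter, size=n)
    cols = m + (gc + 0.5) * pitch_c + rng.uniform(-jitter, jitter, size=n)
    return np.column_stack([rows, cols])


def _permeabilization_prob(config: SimConfig, chol: np.ndarray) -> np.ndarray:
    """Hill-curve permeabilization probability at the per-cell effective dose."""
    if config.slo_dose == 0:
        return np.zeros_like(chol)
    hill = config.perm_hill
    d = config.slo_dose * chol
    dh = d**hill.h
    return dh / (dh + hill.k_dose**hill.h)


def remaining_target_fraction(
    A: np.ndarray, T: np.ndarray, config: SimConfig, k_max: float | None = None
) -> np.ndarray:
    """X/X0 after incubation for delivered antibody A and TRIM21 T."""
    kin = config.deg_kinetics
    km = kin.k_max if k_max is None else k_max
    k = km * (A / (A + kin.K_A)) * (T / (T + kin.K_T))
    f = kin.resistant_fraction
    return f + (1.0 - f) * np.exp(-k * config.incubation_h)


def _phospho_values(
    channel: str, X: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    link = config.phospho_link[channel]
    eps = rng.normal(0.0, link.noise_sd, size=X.shape)
    vals = link.beta * np.power(X, link.gamma) * np.exp(eps)
    cc = config.cc_subpop
    if channel == cc.channel and cc.pi > 0:
        hi = rng.random(X.shape) < cc.pi
        vals = np.where(hi, vals * cc.fold, vals)
    return vals


def _channel_truths(
    config: SimConfig, gt: pd.DataFrame, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-cell true mean intensity for every channel, rounded to integer AU
    (so a noise-free render quantized to 16 bits reproduces them exactly)."""
    n = len(gt)
    X = gt["X"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for ch in config.channels:
        if ch == config.nuclear_channel:
            vals = gt["dna"].to_numpy()
        elif ch == config.ab_channel:
            vals = gt["A"].to_numpy()
        elif ch == config.target_channel:
            vals = X
        elif config.pi_channel is not None and ch == config.pi_channel:
            vals = np.where(gt["died"].to_numpy(), config.died_pi_intensity, 0.0)
        elif ch in config.phospho_link:
            vals = _phospho_values(ch, X, config, rng)
        elif ch in config.baseline_channels:
            mu, sd = config.baseline_channels[ch]
            vals = rng.lognormal(mu, sd, size=n)
        else:
            raise ValueError(
                f"channel {ch!r} has no generative rule: it is none of the nuclear, "
                "antibody, target or PI channel and appears in neither phospho_link "
                "nor baseline_channels"
            )
        out[ch] = np.rint(np.clip(vals, 0, 65535))
    return out


def sample_population(config: SimConfig) -> pd.DataFrame:
    """Draw the ground-truth table for one field.

    Returns one row per cell with latent truths (permeabilization, delivered
    antibody ``A``, TRIM21 ``T``, target before/after ``X0``/``X``), nuclear
    geometry, and the rounded true mean intensity ``true_<channel>`` for every
    configured channel.
    """
    rng = _rng(config, _STREAM_POPULATION)
    n = config.n_cells
    pos = _grid_positions(config, rng)

    chol = rng.lognormal(0.0, config.perm_hill.chol_sigma, size=n)
    p_perm = _permeabilization_prob(config, chol)
    permeabilized = rng.random(n) < p_perm
    reseal_fail = rng.random(n) < config.reseal_fail_prob
    died = permeabilized & reseal_fail
    resealed = permeabilized & ~reseal_fail

    mu_a, sd_a = config.antibody_lognormal
    A = np.where(permeabilized, rng.lognormal(mu_a, sd_a, size=n), 0.0)
    mu_t, sd_t = config.trim21_lognormal
    T = rng.lognormal(mu_t, sd_t, size=n)
    mu_x, sd_x = config.target_lognormal
    X0 = rng.lognormal(mu_x, sd_x, size=n)

    if config.condition == "targeting":
        frac = remaining_target_fraction(A, T, config)
        X = np.where(A > 0, X0 * frac, X0)
    else:
        X = X0.copy()

    a_lo, a_hi = config.nucleus_axes_px
    nuc_a = rng.uniform(a_lo, a_hi, size=n)
    nuc_b = rng.uniform(a_lo, a_hi, size=n)
    theta = rng.uniform(0.0, np.pi, size=n)
    dna = np.clip(rng.normal(config.dna_mean, config.dna_sd, size=n), 50.0, None)

    gt = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "row": pos[:, 0],
            "col": pos[:, 1],
            "nuc_a": nuc_a,
            "nuc_b": nuc_b,
            "theta": theta,
            "dna": dna,
            "chol": chol,
            "permeabilized": permeabilized,
            "resealed": resealed,
            "died": died,
            "A": A,
            "T": T,
            "X0": X0,
            "X": X,
            "condition": config.condition,
        }
    )
    for ch, vals in _channel_truths(config, gt, rng).items():
        gt[f"true_{ch}"] = vals
    return gt


def _radial_falloff(gt: pd.DataFrame, config: SimConfig) -> np.ndarray:
    h, w = config.field_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(gt["row"].to_numpy() - cy, gt["col"].to_numpy() - cx)
    radius = math.hypot(cy, cx)
    g = config.gradient
    sig = 1.0 / (1.0 + np.exp(-g.steepness * (r / radius - g.midpoint_frac)))
    return 1.0 - g.amplitude * sig


def apply_spatial_mode(gt: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Apply the configured spatial delivery pattern to a sampled population.

    ``uniform`` returns the table unchanged. ``center_gradient`` (adherent
    electroporation between central electrodes) thins each cell's
    permeabilization by a radial logistic falloff g(r) of distance from the
    field center; cells losing delivery revert to their undegraded state.
    """
    if config.spatial_mode == "uniform":
        return gt.copy()
    g = _radial_falloff(gt, config)
    rng = _rng(config, _STREAM_SPATIAL)
    keep = rng.random(len(gt)) < g
    out = gt.copy()
    lost = out["permeabilized"].to_numpy() & ~keep
    if not lost.any():
        return out
    # Phospho channels scale as X**gamma, so reverting X -> X0 rescales them
    # without re-drawing their noise.
    X_old = out["X"].to_numpy()
    X0 = out["X0"].to_numpy()
    for ch, link in config.phospho_link.items():
        col = f"true_{ch}"
        if col in out.columns:
            ratio = np.ones_like(X_old)
            np.divide(X0, X_old, out=ratio, where=X_old > 0)
            scaled = out[col].to_numpy(float) * np.power(ratio, link.gamma)
            out.loc[lost, col] = np.rint(scaled[lost])
    out.loc[lost, "permeabilized"] = False
    out.loc[lost, "resealed"] = False
    out.loc[lost, "died"] = False
    out.loc[lost, "A"] = 0.0
    out.loc[lost, "X"] = out.loc[lost, "X0"]
    out.loc[lost, f"true_{config.ab_channel}"] = 0.0
    if config.target_channel in config.channels:
        out.loc[lost, f"true_{config.target_channel}"] = np.rint(out.loc[lost, "X0"])
    if config.pi_channel is not None and f"true_{config.pi_channel}" in out.columns:
        out.loc[lost, f"true_{config.pi_channel}"] = 0.0
    return out


def _int_shift(img: np.ndarray, shift: tuple[int, int], fill: float = 0.0) -> np.ndarray:
    """Exact integer translation moving content by +shift, fill at exposed borders."""
    dy, dx = int(shift[0]), int(shift[1])
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def render_labels(gt: pd.DataFrame, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize ground-truth nucleus and cell label images (cell = nucleus
    thickened by ``cyto_radius_px``, clipped by nearest-nucleus assignment)."""
    shape = config.field_shape
    nuc = np.zeros(shape, dtype=np.int32)
    shrink = config.died_nucleus_shrink
    for row in gt.itertuples():
        a, b = row.nuc_a, row.nuc_b
        if row.died:
            a, b = a * shrink, b * shrink
        rr, cc = draw_ellipse(row.row, row.col, a, b, shape=shape, rotation=row.theta)
        nuc[rr, cc] = row.cell_id
    cells = expand_labels(nuc, distance=config.cyto_radius_px)
    return nuc, cells


def render_rounds(gt: pd.DataFrame, config: SimConfig, field_id: str = "field_000") -> ImageSet:
    """Render the population as a multi-round ImageSet.

    Per round: the scene (with bleaching residue from the previous round's
    matching channel slot) is translated by an integer stage drift drawn from
    round(N(0, shift_px_sd)), then background plane + illumination gradient,
    Poisson shot noise and Gaussian read noise are applied and the result is
    clipped to unsigned 16 bits. Round 1 has zero drift by construction.
    """
    h, w = config.field_shape
    inside = (
        (gt["row"] >= 0) & (gt["row"] < h) & (gt["col"] >= 0) & (gt["col"] < w)
    )
    if not bool(inside.all()):
        raise ValueError("cell centers fall outside the field; cannot render")

    nuc, cells = render_labels(gt, config)
    nuc_mask = nuc > 0
    cyto = np.where(nuc_mask, 0, cells)

    max_id = int(gt["cell_id"].max()) if len(gt) else 0

    def value_grid(col: str, region: str, scale: float = 1.0) -> np.ndarray:
        # per-cell values are integers in AU; any scaling is re-rounded so the
        # noise-free 16-bit render reproduces region means exactly
        lut = np.zeros(max_id + 1)
        lut[gt["cell_id"].to_numpy()] = np.rint(scale * gt[col].to_numpy(float))
        if region == "nucleus":
            return lut[nuc]
        if region == "cell":
            return lut[cells]
        if region == "cyto":
            return lut[cyto]
        raise ValueError(region)

    def base_scene(ch: str) -> np.ndarray:
        col = f"true_{ch}"
        if ch == config.nuclear_channel:
            return value_grid(col, "nucleus")
        if ch == config.ab_channel:
            return value_grid(col, "cell")
        if config.pi_channel is not None and ch == config.pi_channel:
            return value_grid(col, "nucleus")
        if ch == config.target_channel:
            return value_grid(col, "cyto") + value_grid(
                col, "nucleus", scale=config.target_nuclear_ratio
            )
        return value_grid(col, "cyto")

    bases = {ch: base_scene(ch) for ch in config.channels}

    rng = _rng(config, _STREAM_RENDER)
    shifts: list[tuple[int, int]] = [(0, 0)]
    for _ in range(1, len(config.rounds)):
        dy, dx = np.rint(rng.normal(0.0, config.shift_px_sd, size=2)).astype(int)
        shifts.append((int(dy), int(dx)))

    noise = config.noise
    plane = noise.background + noise.gradient * (np.arange(w) / max(w - 1, 1))
    plane = np.broadcast_to(plane, (h, w))

    rounds: list[dict[str, np.ndarray]] = []
    prev_signal: list[np.ndarray] = []
    for r_idx, chans in enumerate(config.rounds):
        signals: list[np.ndarray] = []
        grids: dict[str, np.ndarray] = {}
        for slot, ch in enumerate(chans):
            sig = bases[ch].copy()
            if r_idx > 0 and config.bleach_carryover > 0 and slot < len(prev_signal):
                sig += config.bleach_carryover * prev_signal[slot]
            signals.append(sig)
            img = _int_shift(sig, shifts[r_idx]) + plane
            if noise.shot:
                img = rng.poisson(img).astype(np.float64)
            if noise.read_sd > 0:
                img = img + rng.normal(0.0, noise.read_sd, size=img.shape)
            grids[ch] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        prev_signal = signals
        rounds.append(grids)

    return ImageSet(
        rounds=rounds,
        pixel_um=config.pixel_um,
        field_id=field_id,
        true_shifts=[(float(dy), float(dx)) for dy, dx in shifts],
    )


def simulate_field(config: SimConfig, field_id: str = "field_000") -> tuple[pd.DataFrame, ImageSet]:
    """Sample a population, apply the spatial mode, and render it."""
    gt = sample_population(config)
    gt = apply_spatial_mode(gt, config)
    return gt, render_rounds(gt, config, field_id=field_id)


# --------------------------------------------------------------------------
# Calibration: preset populations are tuned so their latent bulk statistics
# match measured bulk values (western-blot equivalents), which the image
# pipeline must then recover end to end.
# --------------------------------------------------------------------------


def _calibration_latents(config: SimConfig, n: int, seed: int):
    rng = np.random.default_rng([_STREAM_POPULATION, seed])
    chol = rng.lognormal(0.0, config.perm_hill.chol_sigma, size=n)
    p = _permeabilization_prob(config, chol)
    perm = rng.random(n) < p
    died = perm & (rng.random(n) < config.reseal_fail_prob)
    mu_a, sd_a = config.antibody_lognormal
    A = np.where(perm, rng.lognormal(mu_a, sd_a, size=n), 0.0)
    mu_t, sd_t = config.trim21_lognormal
    T = rng.lognormal(mu_t, sd_t, size=n)
    mu_x, sd_x = config.target_lognormal
    X0 = rng.lognormal(mu_x, sd_x, size=n)
    alive = ~died  # non-resealed cells are excluded from calibration populations
    return A[alive], T[alive], X0[alive]


def expected_bulk_knockdown(
    config: SimConfig,
    k_max: float | None = None,
    n: int = 50_000,
    seed: int = _CALIBRATION_SEED,
) -> float:
    """Monte-Carlo population-level knockdown 1 - E[X | targeting]/E[X | NC],
    averaged over all (resealed) cells — the western-blot-equivalent readout."""
    A, T, X0 = _calibration_latents(config, n, seed)
    frac = remaining_target_fraction(A, T, config, k_max=k_max)
    X = np.where(A > 0, X0 * frac, X0)
    return 1.0 - float(X.mean() / X0.mean())


def knockdown_ceiling(
    config: SimConfig, n: int = 50_000, seed: int = _CALIBRATION_SEED
) -> float:
    """Largest achievable bulk knockdown: permeabilized mass times (1 - f_res)."""
    A, T, X0 = _calibration_latents(config, n, seed)
    f = config.deg_kinetics.resistant_fraction
    X_inf = np.where(A > 0, X0 * f, X0)
    return 1.0 - float(X_inf.mean() / X0.mean())


def calibrate_knockdown(
    config: SimConfig,
    target_bulk_fraction: float,
    n: int = 50_000,
    seed: int = _CALIBRATION_SEED,
) -> SimConfig:
    """Return a config whose ``k_max`` yields the requested expected bulk
    knockdown, by monotone 1D root finding on a fixed-seed Monte-Carlo
    population. Raises if the target exceeds the permeabilization ceiling."""
    if not 0.0 <= target_bulk_fraction < 1.0:
        raise ValueError("target_bulk_fraction must be in [0, 1)")
    if target_bulk_fraction == 0.0:
        return config.replace(
            deg_kinetics=dataclasses.replace(config.deg_kinetics, k_max=0.0)
        )
    ceiling = knockdown_ceiling(config, n=n, seed=seed)
    if target_bulk_fraction >= ceiling - 1e-3:
        raise ValueError(
            f"bulk knockdown {target_bulk_fraction:.3f} unreachable: ceiling is "
            f"{ceiling:.3f} (permeabilized fraction x (1 - resistant_fraction))"
        )
    A, T, X0 = _calibration_latents(config, n, seed)

    def gap(log_k: float) -> float:
        frac = remaining_target_fraction(A, T, config, k_max=math.exp(log_k))
        X = np.where(A > 0, X0 * frac, X0)
        return (1.0 - X.mean() / X0.mean()) - target_bulk_fraction

    log_k = brentq(gap, math.log(1e-6), math.log(1e6), xtol=1e-10)
    return config.replace(
        deg_kinetics=dataclasses.replace(config.deg_kinetics, k_max=math.exp(log_k))
    )


def calibrate_permeabilization(
    config: SimConfig,
    target_fraction: float,
    n: int = 200_000,
    seed: int = _CALIBRATION_SEED,
) -> SimConfig:
    """Return a config whose Hill half-saturation dose makes the expected
    permeabilized fraction at ``config.slo_dose`` equal ``target_fraction``."""
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    if config.slo_dose <= 0:
        raise ValueError("cannot calibrate permeabilization at zero SLO dose")
    rng = np.random.default_rng([_STREAM_POPULATION, seed])
    chol = rng.lognormal(0.0, config.perm_hill.chol_sigma, size=n)

    def gap(log_k: float) -> float:
        hill = dataclasses.replace(config.perm_hill, k_dose=math.exp(log_k))
        cfg = config.replace(perm_hill=hill)
        return float(_permeabilization_prob(cfg, chol).mean()) - target_fraction

    lo = math.log(config.slo_dose) - 8.0
    hi = math.log(config.slo_dose) + 8.0
    log_k = brentq(gap, lo, hi, xtol=1e-12)
    return config.replace(
        perm_hill=dataclasses.replace(config.perm_hill, k_dose=math.exp(log_k))
    )
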