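"""Ground-truthed synthetic microscopy of miRNA-mediated silencing.

The generator emulates the biology of a pulse-chase reporter experiment in
adherent human cells:

* a transcription pulse produces ``SunTag`` reporter mRNAs (and, for the decay
  design, internal-control ``Fluc`` mRNAs from the same bidirectional
  promoter), with per-cell copy numbers drawn from a truncated negative
  binomial (median ~40, max ~100 per cell);
* mRNAs export from the nucleus with first-order kinetics — the probability
  that a transcript is cytoplasmic by chase time ``t`` is
  ``1 − exp(−k_export · (t + pulse_min))``, the pulse offset accounting for
  transcripts being made during the induction window;
* in the ``+miR-21`` condition each cytoplasmic reporter is RISC-bound with
  probability ``p_risc_bind`` from t = 0; the seed-mutant control binds only
  with the (default zero) ``p_risc_false`` — its observed ~10% RISC-positive
  baseline instead emerges downstream from chance colocalization with the
  ~2000 free AGO spots per cell;
* translation is independent of RISC before ``repression_onset_min`` and
  stepped down for RISC-bound mRNAs afterwards; translated mRNAs carry
  ``1 + Poisson(mean − 1)`` ribosomes;
* for the decay design (reporter without the anti-deadenylation element),
  cytoplasmic reporters in the +miR-21 condition survive with probability
  ``decay_survival`` once ``t ≥ decay_onset_min``;
* free SunTag peptides (~250 SunTag spots per cell in total) and free AGO
  (~2000 spots per cell) are scattered uniformly through the cytoplasm; spots
  marking translation/RISC on an mRNA sit at the mRNA position plus isotropic
  60-nm jitter, truncated at 3σ so designed partners always fall inside the
  colocalization gates.

Two output paths share one truth table: :func:`emit_spot_tables` produces
noisy spot tables directly (fast path, format-identical to the detector's
output), and :func:`render_field` rasterizes 3D image stacks with an
anisotropic Gaussian PSF, Poisson shot noise and Gaussian read noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from silencescope.types import CellGeometry, ImageStack, SPOT_COLUMNS

#: channels present in each experiment design
DESIGN_CHANNELS = {
    "decay": ("mrna", "fluc"),
    "translation": ("mrna", "suntag"),
    "risc": ("mrna", "ago"),
    "triple": ("mrna", "suntag", "ago"),
}

_SPECIES_CHANNEL = {
    "reporter_mRNA": "mrna",
    "fluc_mRNA": "fluc",
    "suntag_on_mRNA": "suntag",
    "suntag_free": "suntag",
    "ago_on_mRNA": "ago",
    "ago_free": "ago",
}

TRUTH_COLUMNS = [
    "spot_id", "cell_id", "species", "z_nm", "y_nm", "x_nm", "intensity",
    "compartment", "linked_mrna_id", "ribosome_count", "translated", "risc_bound",
]


@dataclass
class SimulationConfig:
    """All knobs of the generative model; defaults are the study conditions.

    Counts and rates mirror the published summaries: reporter copy number
    truncated-NB with median ~40 / max 100; ~250 SunTag IF spots and ~2000 AGO
    IF spots per cell; translation repression stepping in at 30 min and decay
    (survival 0.5) at 60 min of the chase.
    """

    # experiment identity
    design: str = "triple"              # decay | translation | risc | triple
    condition: str = "miR21"            # miR21 | mutant
    time_min: float = 0.0               # chase time after the pulse (0/30/60)
    n_cells: int = 50
    seed: int = 0

    # field geometry (virtual voxel grid; z extent bounds spot z positions)
    field_shape: tuple[int, int, int] = (25, 1920, 1920)   # (z, y, x) voxels
    voxel_size_xy_nm: float = 107.5
    voxel_size_z_nm: float = 200.0
    cell_radii_um: tuple[float, float] = (12.0, 10.0)      # (ry, rx) semi-axes
    nucleus_radii_um: tuple[float, float] = (5.5, 4.5)

    # copy numbers
    mrna_mean: float = 45.0             # NB mean before truncation
    mrna_dispersion: float = 4.0        # NB size r (smaller = more variable)
    mrna_max: int = 100                 # hard truncation
    fluc_mean: float = 45.0
    n_free_suntag: int = 225            # free peptides; ~250 SunTag spots/cell total
    n_ago_spots: int = 2000             # free AGO spots per cell

    # kinetics
    k_export: float = 0.012             # per-min nuclear-export rate
    pulse_min: float = 30.0             # transcription-pulse duration added to t
    p_risc_bind: float = 0.5            # +miR-21 cytoplasmic binding probability
    p_risc_false: float = 0.0           # mutant linked-binding probability
    repression_onset_min: float = 30.0
    p_translated_active: float = 0.65
    p_translated_repressed: float = 0.15
    decay_onset_min: float = 60.0
    decay_survival: float = 0.5

    # intensities (arbitrary units; 1.0 = one peptide for SunTag)
    ribosome_mean_active: float = 8.0
    ribosome_mean_repressed: float = 1.0
    intensity_sigma_log: float = 0.3    # lognormal width of unit intensities
    mrna_intensity_median: float = 1.0

    # measurement model
    partner_jitter_nm: float = 60.0     # isotropic σ of on-mRNA partner offset
    loc_noise_nm: float = 20.0          # per-axis localization error (fast path)
    intensity_meas_cv: float = 0.05     # multiplicative intensity perturbation
    drift_nm: dict = field(default_factory=dict)   # channel -> (dz, dy, dx) nm
    psf_sigma_xy_nm: float = 130.0
    psf_sigma_z_nm: float = 300.0
    shot_scale: float = 1.0             # photons per count; 0 disables shot noise
    read_noise_sd: float = 2.0
    background_level: float = 20.0      # cytoplasmic haze (counts)
    dapi_level: float = 150.0
    render_intensity_scale: float = 2000.0   # counts per intensity unit

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.design not in DESIGN_CHANNELS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.condition not in ("miR21", "mutant"):
            raise ValueError(f"unknown condition {self.condition!r}")
        for name in ("p_risc_bind", "p_risc_false", "p_translated_active",
                     "p_translated_repressed", "decay_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("k_export", "pulse_min", "mrna_mean", "mrna_dispersion",
                     "fluc_mean", "partner_jitter_nm", "loc_noise_nm",
                     "psf_sigma_xy_nm", "psf_sigma_z_nm", "read_noise_sd",
                     "ribosome_mean_active", "ribosome_mean_repressed",
                     "intensity_sigma_log", "shot_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_cells, self.n_free_suntag + 1, self.n_ago_spots + 1) < 1:
            raise ValueError("counts must be non-negative (n_cells >= 1)")
        ny_r, nx_r = self.nucleus_radii_um
        cy_r, cx_r = self.cell_radii_um
        if ny_r >= cy_r or nx_r >= cx_r:
            raise ValueError("nucleus must be strictly smaller than the cell")

    # -- derived geometry --------------------------------------------------
    @property
    def channels(self) -> tuple[str, ...]:
        return DESIGN_CHANNELS[self.design]

    @property
    def cell_radii_px(self) -> tuple[float, float]:
        return tuple(1000.0 * r / self.voxel_size_xy_nm for r in self.cell_radii_um)

    @property
    def nucleus_radii_px(self) -> tuple[float, float]:
        return tuple(1000.0 * r / self.voxel_size_xy_nm for r in self.nucleus_radii_um)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_shape"] = list(self.field_shape)
        d["cell_radii_um"] = list(self.cell_radii_um)
        d["nucleus_radii_um"] = list(self.nucleus_radii_um)
        d["drift_nm"] = {ch: [float(v) for v in vec]
                         for ch, vec in self.drift_nm.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("field_shape", "cell_radii_um", "nucleus_radii_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# truth sampling
# ---------------------------------------------------------------------------

def _expression_level(rng: np.random.Generator, mean: float, r: float) -> float:
    """Per-cell induction strength: the Gamma mixing level of a negative
    binomial with mean ``mean`` and size ``r``.  Reporter and internal-control
    copy numbers are Poisson draws around one shared level, reflecting their
    common (bidirectional) promoter — per-cell count *ratios* are therefore
    much tighter than the marginal copy-number distribution."""
    return float(rng.gamma(r, mean / r))


def _copy_number(rng: np.random.Generator, level: float, vmax: int) -> int:
    """Poisson copy number at a given expression level, truncated at vmax
    (marginally negative binomial with median ~40 at the defaults)."""
    n = int(rng.poisson(level))
    for _ in range(100):
        if n <= vmax:
            break
        n = int(rng.poisson(level))
    return min(n, vmax)


def _sample_in_ellipse(rng: np.random.Generator, center: tuple[float, float],
                       radii: tuple[float, float], n: int,
                       exclude_radii: tuple[float, float] | None = None,
                       shrink: float = 0.98) -> np.ndarray:
    """Uniform (y, x) pixel positions inside an ellipse, optionally outside an
    inner concentric ellipse (rejection sampling).  ``shrink`` keeps samples
    strictly inside the boundary."""
    cy, cx = center
    ry, rx = radii[0] * shrink, radii[1] * shrink
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        u = rng.uniform(-1, 1, size=(m, 2))
        keep = (u ** 2).sum(axis=1) <= 1.0
        pts = u[keep]
        y = cy + pts[:, 0] * ry
        x = cx + pts[:, 1] * rx
        if exclude_radii is not None:
            iry, irx = exclude_radii
            inside_inner = ((y - cy) / iry) ** 2 + ((x - cx) / irx) ** 2 <= 1.0
            y, x = y[~inside_inner], x[~inside_inner]
        take = min(n - got, len(y))
        out[got:got + take, 0] = y[:take]
        out[got:got + take, 1] = x[:take]
        got += take
    return out


def _grid_centers(config: SimulationConfig) -> np.ndarray:
    """Lay cells out on a grid inside the field; error if they cannot fit."""
    ry, rx = config.cell_radii_px
    _, ny, nx = config.field_shape
    pitch_y, pitch_x = 2.0 * ry * 1.05, 2.0 * rx * 1.05
    cols = int(nx // pitch_x)
    rows = int(ny // pitch_y)
    if cols * rows < config.n_cells:
        raise ValueError(
            f"field {config.field_shape} too small for {config.n_cells} cells "
            f"of radius {config.cell_radii_um} um; fits {cols * rows}")
    rows_used = int(np.ceil(config.n_cells / cols))
    off_y = (ny - rows_used * pitch_y) / 2.0
    off_x = (nx - min(config.n_cells, cols) * pitch_x) / 2.0
    centers = []
    for i in range(config.n_cells):
        r, c = divmod(i, cols)
        centers.append((off_y + (r + 0.5) * pitch_y, off_x + (c + 0.5) * pitch_x))
    return np.asarray(centers)


def sample_cell_population(config: SimulationConfig) -> tuple[list[CellGeometry], pd.DataFrame]:
    """Draw per-cell ground truth for one (condition, time) field.

    Returns the cell geometries (analytic ellipses on a virtual grid) and a
    truth table with one row per fluorescent molecule/spot.  A single seeded
    RNG stream is split per cell, so regenerating any prefix of cells is
    reproducible.
    """
    config.validate()
    centers = _grid_centers(config)
    cell_streams = np.random.SeedSequence(config.seed).spawn(config.n_cells)

    z_max_nm = config.field_shape[0] * config.voxel_size_z_nm
    p_cyto = 1.0 - np.exp(-config.k_export * (config.time_min + config.pulse_min))
    p_bind = config.p_risc_bind if config.condition == "miR21" else config.p_risc_false
    decay_on = (config.design == "decay" and config.condition == "miR21"
                and config.time_min >= config.decay_onset_min)
    repression_on = config.time_min >= config.repression_onset_min
    channels = config.channels
    jitter_cap = 3.0 * config.partner_jitter_nm

    geoms: list[CellGeometry] = []
    blocks: list[pd.DataFrame] = []
    spot_id = 0

    def _unit_lognormal(rng, n, median=1.0):
        return median * np.exp(rng.normal(0.0, config.intensity_sigma_log, size=n))

    def _block(cell_id, species, z, y, x, intensity, compartment, linked, ribo, translated, bound):
        nonlocal spot_id
        n = len(z)
        df = pd.DataFrame({
            "spot_id": np.arange(spot_id, spot_id + n),
            "cell_id": cell_id, "species": species,
            "z_nm": z, "y_nm": y, "x_nm": x, "intensity": intensity,
            "compartment": compartment, "linked_mrna_id": linked,
            "ribosome_count": ribo, "translated": translated, "risc_bound": bound,
        }, columns=TRUTH_COLUMNS)
        spot_id += n
        return df

    for cell_id, (center, ss) in enumerate(zip(centers, cell_streams)):
        rng = np.random.default_rng(ss)
        geom = CellGeometry(
            cell_id=cell_id, field_shape_yx=config.field_shape[1:],
            pixel_size_nm=config.voxel_size_xy_nm,
            center_px=tuple(center), cell_radii_px=config.cell_radii_px,
            nucleus_radii_px=config.nucleus_radii_px)
        geoms.append(geom)

        def _place(n, compartment, rng=rng, center=center):
            if compartment == "nuclear":
                yx = _sample_in_ellipse(rng, center, config.nucleus_radii_px, n)
            else:
                yx = _sample_in_ellipse(rng, center, config.cell_radii_px, n,
                                        exclude_radii=config.nucleus_radii_px)
            z = rng.uniform(0.2 * z_max_nm, 0.8 * z_max_nm, size=n)
            y = (yx[:, 0]) * config.voxel_size_xy_nm
            x = (yx[:, 1]) * config.voxel_size_xy_nm
            return z, y, x

        # ---- reporter mRNAs ----------------------------------------------
        level = _expression_level(rng, config.mrna_mean, config.mrna_dispersion)
        n_mrna = _copy_number(rng, level, config.mrna_max)
        cyto = rng.random(n_mrna) < p_cyto
        if decay_on:
            cyto_idx = np.flatnonzero(cyto)
            survive = rng.random(cyto_idx.size) < config.decay_survival
            keep = np.ones(n_mrna, bool)
            keep[cyto_idx[~survive]] = False
            cyto = cyto[keep]
            n_mrna = int(keep.sum())

        bound = np.zeros(n_mrna, bool)
        bound[cyto] = rng.random(int(cyto.sum())) < p_bind
        p_tr = np.where(bound & repression_on,
                        config.p_translated_repressed, config.p_translated_active)
        translated = (rng.random(n_mrna) < p_tr) & cyto
        ribo = np.zeros(n_mrna)
        mean_r = np.where(bound & repression_on,
                          config.ribosome_mean_repressed, config.ribosome_mean_active)
        ribo[translated] = 1 + rng.poisson(np.maximum(mean_r[translated] - 1.0, 0.0))

        zs_n, ys_n, xs_n = _place(int((~cyto).sum()), "nuclear")
        zs_c, ys_c, xs_c = _place(int(cyto.sum()), "cytoplasmic")
        z = np.empty(n_mrna); y = np.empty(n_mrna); x = np.empty(n_mrna)
        z[~cyto], y[~cyto], x[~cyto] = zs_n, ys_n, xs_n
        z[cyto], y[cyto], x[cyto] = zs_c, ys_c, xs_c
        inten = _unit_lognormal(rng, n_mrna, config.mrna_intensity_median)

        mrna_ids = np.arange(spot_id, spot_id + n_mrna)
        blocks.append(_block(
            cell_id, "reporter_mRNA", z, y, x, inten,
            np.where(cyto, "cytoplasmic", "nuclear"),
            np.full(n_mrna, np.nan), np.full(n_mrna, np.nan), translated, bound))

        def _jitter(rng, n):
            v = rng.normal(0.0, config.partner_jitter_nm, size=(n, 3))
            norm = np.linalg.norm(v, axis=1, keepdims=True)
            over = norm[:, 0] > jitter_cap
            if over.any():
                v[over] *= jitter_cap / norm[over]
            return v

        # ---- partner spots on mRNAs --------------------------------------
        if "suntag" in channels:
            idx = np.flatnonzero(translated)
            jit = _jitter(rng, idx.size)
            unit = _unit_lognormal(rng, idx.size)
            blocks.append(_block(
                cell_id, "suntag_on_mRNA",
                z[idx] + jit[:, 0], y[idx] + jit[:, 1], x[idx] + jit[:, 2],
                ribo[idx] * unit, "cytoplasmic", mrna_ids[idx].astype(float),
                ribo[idx], np.ones(idx.size, bool), bound[idx]))
        if "ago" in channels:
            idx = np.flatnonzero(bound)
            jit = _jitter(rng, idx.size)
            unit = _unit_lognormal(rng, idx.size)
            blocks.append(_block(
                cell_id, "ago_on_mRNA",
                z[idx] + jit[:, 0], y[idx] + jit[:, 1], x[idx] + jit[:, 2],
                unit, "cytoplasmic", mrna_ids[idx].astype(float),
                np.full(idx.size, np.nan), translated[idx], np.ones(idx.size, bool)))

        # ---- internal-control Fluc mRNAs ---------------------------------
        if "fluc" in channels:
            n_fluc = _copy_number(rng, level * config.fluc_mean / config.mrna_mean,
                                  config.mrna_max)
            f_cyto = rng.random(n_fluc) < p_cyto
            fz = np.empty(n_fluc); fy = np.empty(n_fluc); fx = np.empty(n_fluc)
            fz[~f_cyto], fy[~f_cyto], fx[~f_cyto] = _place(int((~f_cyto).sum()), "nuclear")
            fz[f_cyto], fy[f_cyto], fx[f_cyto] = _place(int(f_cyto.sum()), "cytoplasmic")
            fint = _unit_lognormal(rng, n_fluc, config.mrna_intensity_median)
            blocks.append(_block(
                cell_id, "fluc_mRNA", fz, fy, fx, fint,
                np.where(f_cyto, "cytoplasmic", "nuclear"),
                np.full(n_fluc, np.nan), np.full(n_fluc, np.nan),
                np.zeros(n_fluc, bool), np.zeros(n_fluc, bool)))

        # ---- free cytoplasmic spots --------------------------------------
        for species, n_free in (("suntag_free", config.n_free_suntag),
                                ("ago_free", config.n_ago_spots)):
            if _SPECIES_CHANNEL[species] not in channels or n_free == 0:
                continue
            fz, fy, fx = _place(n_free, "cytoplasmic")
            unit = _unit_lognormal(rng, n_free)
            blocks.append(_block(
                cell_id, species, fz, fy, fx, unit, "cytoplasmic",
                np.full(n_free, np.nan), np.full(n_free, np.nan),
                np.zeros(n_free, bool), np.zeros(n_free, bool)))

    if blocks:
        truth = pd.concat(blocks, ignore_index=True)
    else:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    return geoms, truth


# ---------------------------------------------------------------------------
# fast path: noisy spot tables
# ---------------------------------------------------------------------------

def emit_spot_tables(truth: pd.DataFrame, config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Turn the truth table into per-channel spot tables, bypassing rendering.

    Positions get per-axis Gaussian localization noise plus the channel's
    drift; intensities get a multiplicative lognormal perturbation.  Output
    columns match the detector's :func:`~silencescope.detect.filter_spots`,
    with ``cell_id``/``compartment`` unset (the segmentation stage assigns
    them) and a ``truth_id`` provenance column for validation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    tables: dict[str, pd.DataFrame] = {}
    for channel in config.channels:
        species = [s for s, ch in _SPECIES_CHANNEL.items() if ch == channel]
        sub = truth[truth.species.isin(species)]
        n = len(sub)
        pos = sub[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)
        if config.loc_noise_nm > 0:
            pos = pos + rng.normal(0.0, config.loc_noise_nm, size=(n, 3))
        drift = np.asarray(config.drift_nm.get(channel, (0.0, 0.0, 0.0)), dtype=float)
        pos = pos + drift
        inten = sub["intensity"].to_numpy(dtype=float)
        if config.intensity_meas_cv > 0:
            inten = inten * np.exp(rng.normal(0.0, config.intensity_meas_cv, size=n))
        tables[channel] = pd.DataFrame({
            "spot_id": np.arange(n),
            "channel": channel,
            "z_nm": pos[:, 0], "y_nm": pos[:, 1], "x_nm": pos[:, 2],
            "amplitude": inten,
            "integrated_intensity": inten,
            "sigma_xy_nm": config.psf_sigma_xy_nm,
            "sigma_z_nm": config.psf_sigma_z_nm,
            "background": 0.0, "residual": 0.0,
            "cell_id": -1, "compartment": "unassigned",
            "truth_id": sub["spot_id"].to_numpy(),
        })
    return tables


# ---------------------------------------------------------------------------
# slow path: rendered image stacks
# ---------------------------------------------------------------------------

def _render_spots(shape, pos_vox, amplitudes, sig_vox):
    """Accumulate anisotropic 3D Gaussians into a float field (local windows)."""
    img = np.zeros(shape, dtype=np.float64)
    nz, ny, nx = shape
    sz, sy, sx = sig_vox
    wz, wy, wx = (int(np.ceil(4 * s)) for s in (sz, sy, sx))
    for (z, y, x), a in zip(pos_vox, amplitudes):
        iz, iy, ix = int(round(z)), int(round(y)), int(round(x))
        z0, z1 = max(iz - wz, 0), min(iz + wz + 1, nz)
        y0, y1 = max(iy - wy, 0), min(iy + wy + 1, ny)
        x0, x1 = max(ix - wx, 0), min(ix + wx + 1, nx)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        gz = np.exp(-0.5 * ((np.arange(z0, z1) - z) / sz) ** 2)
        gy = np.exp(-0.5 * ((np.arange(y0, y1) - y) / sy) ** 2)
        gx = np.exp(-0.5 * ((np.arange(x0, x1) - x) / sx) ** 2)
        img[z0:z1, y0:y1, x0:x1] += a * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return img


def render_field(truth: pd.DataFrame, geometry: list[CellGeometry],
                 config: SimulationConfig, channels: tuple[str, ...] | None = None,
                 ) -> dict[str, ImageStack]:
    """Rasterize truth into per-channel 3D stacks (plus ``dapi``/``background``).

    Each spot becomes an anisotropic 3D Gaussian whose voxel-summed signal
    equals ``intensity * render_intensity_scale``; channel drift is applied as
    a sub-voxel shift of that channel's coordinates before rendering.  Noise:
    Poisson shot noise (if ``shot_scale > 0``) then additive Gaussian read
    noise, clipped at zero.
    """
    if channels is None:
        channels = tuple(config.channels) + ("dapi", "background")
    shape = tuple(config.field_shape)
    vx, vz = config.voxel_size_xy_nm, config.voxel_size_z_nm
    sig_vox = (config.psf_sigma_z_nm / vz, config.psf_sigma_xy_nm / vx,
               config.psf_sigma_xy_nm / vx)
    # amplitude such that the voxel-integrated signal equals the intensity
    amp_per_unit = (config.render_intensity_scale * vx * vx * vz
                    / ((2 * np.pi) ** 1.5 * config.psf_sigma_xy_nm ** 2
                       * config.psf_sigma_z_nm))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1A6E]))

    cell_mask = np.zeros(shape[1:], dtype=bool)
    nuc_mask = np.zeros(shape[1:], dtype=bool)
    for g in geometry:
        cell_mask |= g.cell_mask
        nuc_mask |= g.nucleus_mask
    haze2d = ndimage.gaussian_filter(cell_mask.astype(float), sigma=3.0)
    dapi2d = ndimage.gaussian_filter(nuc_mask.astype(float), sigma=2.0)

    stacks: dict[str, ImageStack] = {}
    for channel in channels:
        if channel == "dapi":
            clean = np.broadcast_to(config.dapi_level * dapi2d, shape).copy()
        elif channel == "background":
            clean = np.broadcast_to(config.background_level * haze2d, shape).copy()
        else:
            species = [s for s, ch in _SPECIES_CHANNEL.items() if ch == channel]
            sub = truth[truth.species.isin(species)]
            drift = np.asarray(config.drift_nm.get(channel, (0.0, 0.0, 0.0)), dtype=float)
            pos_nm = sub[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float) + drift
            pos_vox = pos_nm / np.array([vz, vx, vx]) - 0.5
            inb = np.all((pos_vox > -0.5) & (pos_vox < np.array(shape) - 0.5), axis=1)
            if (~inb).any():
                warnings.warn(f"{int((~inb).sum())} {channel} spots outside the field; clipped",
                              stacklevel=2)
            amps = sub["intensity"].to_numpy(dtype=float)[inb] * amp_per_unit
            clean = _render_spots(shape, pos_vox[inb], amps, sig_vox)
            clean += config.background_level * 0.5 * haze2d[None, :, :]
        if config.shot_scale > 0:
            noisy = rng.poisson(np.clip(clean, 0, None) * config.shot_scale) / config.shot_scale
        else:
            noisy = clean.copy()
        if config.read_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, config.read_noise_sd, size=shape)
        stacks[channel] = ImageStack(np.clip(noisy, 0, None), voxel_size_xy_nm=vx,
                                     voxel_size_z_nm=vz, channel_name=channel)
    return stacks
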