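"""Synthetic data generators with known ground truth.

Four generators mirror the four experimental data streams the analysis
stages consume:

* :func:`gen_membrane_trajectory` — lipid markers of four species diffusing
  in two leaflets of a periodic membrane patch around a slowly rotating
  amphipathic helix, with species-specific enrichment sites fixed in the
  helix frame (Metropolis dynamics on Gaussian-well potentials).
* :func:`gen_cell_image` — a cell with a bright plasma-membrane ring over a
  dimmer cytosol on a dark background, blurred and noised, with the analytic
  relative F_PM as ground truth.
* :func:`gen_progress_curve_set` — real-time kinase progress curves (NBD
  fluorescence vs time) driven by an allosteric sigmoidal velocity law,
  with matched 0 mol% substrate background curves and probe standards.
* :func:`gen_calibration_spectra` — three-channel spectral readings with
  known donor/acceptor bleed-through fractions and an injected FRET
  component.

Every generator is a pure function of its parameter object, including the
seed: identical parameters give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .trajectory import EMBEDDED, OPPOSING, LipidTrajectory, wrap_coords

# Membrane composition of the simulated bilayer: 69/20/10/1 mol% =
# 414 POPC, 120 cholesterol, 60 DOPS, 6 PI4P molecules per membrane.
DEFAULT_SPECIES_COUNTS = {"POPC": 414, "CHOL": 120, "DOPS": 60, "PI4P": 6}

# Lateral diffusion coefficients, Å²/ps. Chosen at the fast end of reported
# lipid mobility (~2e-7 cm²/s) so that successive 250 ps samples decorrelate
# at the 1 Å bin scale and maps are well sampled within ~500 ns trajectories;
# atomistic membranes mix more slowly and need proportionally longer runs.
DEFAULT_DIFFUSION = {"POPC": 2e-3, "CHOL": 3e-3, "DOPS": 2e-3, "PI4P": 2e-3}


@dataclass
class EnrichmentSite:
    """A Gaussian-well lipid interaction site fixed in the helix frame.

    ``position`` is (x, y) in Å in the helix frame (helix axis along x,
    centred at the origin); ``depth`` is the well depth in kT; ``radius``
    the Gaussian width in Å. Only markers of ``species`` in the embedded
    leaflet feel the site.
    """

    position: tuple[float, float]
    species: str
    depth: float = 5.0
    radius: float = 4.0


def _default_sites() -> list[EnrichmentSite]:
    # Two sites on opposite flanks of the helix, both selective for PI4P.
    return [
        EnrichmentSite((6.0, 3.0), "PI4P"),
        EnrichmentSite((-6.0, -3.0), "PI4P"),
    ]


@dataclass
class TrajectoryParams:
    n_frames: int = 2000
    frame_interval: float = 250.0  # ps
    box: tuple[float, float] = (100.0, 100.0)  # Å
    species_counts: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_COUNTS))
    diffusion_coeff: dict = field(default_factory=lambda: dict(DEFAULT_DIFFUSION))
    helix_length: float = 36.0  # Å
    helix_rotational_sigma: float = 0.02  # rad per frame
    enrichment_sites: list = field(default_factory=_default_sites)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        if min(self.box) <= 0:
            raise ValueError("box dimensions must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if any(c < 0 for c in self.species_counts.values()):
            raise ValueError("species counts must be >= 0")
        for s in self.enrichment_sites:
            if s.radius <= 0:
                raise ValueError("site radius must be positive")


def split_leaflets(counts: dict) -> tuple[dict, dict]:
    """Split per-membrane counts evenly across leaflets, odd remainder to the
    embedded (helix-containing) leaflet."""
    emb = {s: (n + 1) // 2 for s, n in counts.items()}
    opp = {s: n // 2 for s, n in counts.items()}
    return emb, opp


def _site_potential(xy: np.ndarray, sites: list[EnrichmentSite], species: str,
                    theta: float, center: np.ndarray, box) -> np.ndarray:
    """Potential energy (kT) at lab positions ``xy`` for one species.

    Site positions are defined in the helix frame and carried into the lab
    frame by the instantaneous helix rotation; distances use the minimum
    image convention.
    """
    u = np.zeros(len(xy))
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s], [s, c]])
    L = np.asarray(box)
    for site in sites:
        if site.species != species:
            continue
        lab = center + R @ np.asarray(site.position)
        d = xy - lab
        d -= np.round(d / L) * L
        r2 = (d ** 2).sum(axis=1)
        u -= site.depth * np.exp(-r2 / (2.0 * site.radius ** 2))
    return u


def _jittered_lattice(rng: np.random.Generator, n: int, box, center) -> np.ndarray:
    """n points on a jittered rectangular lattice spanning the box."""
    L = np.asarray(box, dtype=float)
    ncol = max(int(math.ceil(math.sqrt(n * L[0] / L[1]))), 1)
    nrow = int(math.ceil(n / ncol))
    dx, dy = L[0] / ncol, L[1] / nrow
    cells = np.array([(i, j) for j in range(nrow) for i in range(ncol)], dtype=float)
    # drop surplus cells at random so no box region is systematically short
    cells = cells[rng.permutation(len(cells))[:n]]
    jitter = rng.random((n, 2))
    pts = (cells + jitter) * np.array([dx, dy]) - L / 2.0 + np.asarray(center)
    return pts


def _boltzmann_init(rng: np.random.Generator, n: int, sites, species, theta,
                    center, box) -> np.ndarray:
    """Rejection-sample initial positions from exp(-U) so that time averages
    start in the stationary ensemble despite slow lipid diffusion."""
    total_depth = sum(s.depth for s in sites if s.species == species)
    wmax = math.exp(total_depth) if total_depth > 0 else 1.0
    out = np.empty((0, 2))
    L = np.asarray(box)
    while len(out) < n:
        batch = max(64, 4 * n)
        xy = (rng.random((batch, 2)) - 0.5) * L + center
        w = np.exp(-_site_potential(xy, sites, species, theta, center, box))
        keep = rng.random(batch) < w / wmax
        out = np.vstack([out, xy[keep]])
    return out[:n]


def gen_membrane_trajectory(params: TrajectoryParams) -> LipidTrajectory:
    """Simulate 2D-diffusing lipid markers around a rotating helix.

    Markers perform periodic Gaussian random walks. Species targeted by an
    enrichment site accept or reject each proposed step with the Metropolis
    probability ``min(1, exp(-ΔU))``, where U is the sum of Gaussian wells
    evaluated in the instantaneous helix frame. Sites act only on the
    embedded leaflet; the opposing leaflet never feels them. The helix is a
    rigid rod of backbone markers whose in-plane orientation performs
    rotational diffusion.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    box = params.box
    center = np.array([0.0, 0.0])  # box centred on the origin
    emb_counts, opp_counts = split_leaflets(params.species_counts)

    species_order = list(params.species_counts)
    species_l, leaflet_l, diffus = [], [], []
    for leaf, counts in ((EMBEDDED, emb_counts), (OPPOSING, opp_counts)):
        for sp in species_order:
            species_l += [sp] * counts[sp]
            leaflet_l += [leaf] * counts[sp]
            diffus += [params.diffusion_coeff.get(sp, 8e-4)] * counts[sp]
    species = np.array(species_l, dtype=object)
    leaflet = np.array(leaflet_l, dtype=object)
    sigma_step = np.sqrt(2.0 * np.asarray(diffus) * params.frame_interval)
    M = len(species)

    # helix orientation: rotational diffusion
    theta0 = rng.uniform(-math.pi, math.pi)
    dtheta = rng.normal(0.0, params.helix_rotational_sigma, size=max(params.n_frames - 1, 0))
    thetas = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])

    affected_species = {s.species for s in params.enrichment_sites}

    # Initial positions: jittered lattice per leaflet. An equilibrated fluid
    # membrane has liquid-like short-range order (excluded volume), so lipid
    # starting positions cover the patch evenly rather than with the
    # large-scale clumping of iid-uniform draws.
    xy = np.empty((M, 2))
    for leaf in (EMBEDDED, OPPOSING):
        sel = np.nonzero(leaflet == leaf)[0]
        if sel.size:
            pts = _jittered_lattice(rng, sel.size, box, center)
            xy[sel] = pts[rng.permutation(sel.size)]
    for sp in sorted(affected_species):
        sel = (species == sp) & (leaflet == EMBEDDED)
        if sel.any():
            xy[sel] = _boltzmann_init(
                rng, int(sel.sum()), params.enrichment_sites, sp, theta0, center, box
            )

    z = np.where(leaflet == EMBEDDED, 18.0, -18.0)

    n_bb = max(int(round(params.helix_length / 1.5)) + 1, 3)
    s_axis = np.linspace(-params.helix_length / 2.0, params.helix_length / 2.0, n_bb)

    if params.n_frames == 0:
        return LipidTrajectory(
            times=np.empty(0), box=box, ids=np.arange(M), species=species,
            leaflet=leaflet, xyz=np.empty((0, M, 3)), backbone=np.empty((0, n_bb, 3)),
            meta={"seed": params.seed},
        )

    xyz = np.empty((params.n_frames, M, 3))
    backbone = np.empty((params.n_frames, n_bb, 3))
    free = ~np.isin(species, list(affected_species)) | (leaflet == OPPOSING)
    moving = ~free

    for f in range(params.n_frames):
        th = thetas[f]
        if f > 0:
            step = rng.normal(0.0, 1.0, size=(M, 2)) * sigma_step[:, None]
            xy[free] += step[free]
            if moving.any():
                for sp in sorted(affected_species):
                    sel = (species == sp) & moving
                    if not sel.any():
                        continue
                    prop = xy[sel] + step[sel]
                    u_old = _site_potential(xy[sel], params.enrichment_sites, sp, th, center, box)
                    u_new = _site_potential(prop, params.enrichment_sites, sp, th, center, box)
                    acc = rng.random(int(sel.sum())) < np.exp(np.minimum(u_old - u_new, 0.0))
                    cur = xy[sel]
                    cur[acc] = prop[acc]
                    xy[sel] = cur
            xy = wrap_coords(xy, box, center)
        xyz[f, :, :2] = xy
        xyz[f, :, 2] = z
        c, s = math.cos(th), math.sin(th)
        backbone[f, :, 0] = center[0] + c * s_axis
        backbone[f, :, 1] = center[1] + s * s_axis
        backbone[f, :, 2] = 14.0

    times = np.arange(params.n_frames) * params.frame_interval
    return LipidTrajectory(
        times=times, box=box, ids=np.arange(M), species=species, leaflet=leaflet,
        xyz=xyz, backbone=backbone,
        meta={"seed": params.seed, "thetas": thetas, "sites": params.enrichment_sites},
    )


# --------------------------------------------------------------------- images

@dataclass
class ImageParams:
    image_size: tuple[int, int] = (256, 256)
    cell_center: tuple[float, float] = (128.0, 128.0)
    cell_radius: float = 70.0
    ring_width: float = 8.0
    pm_intensity: float = 200.0
    cytosol_intensity: float = 60.0
    background: float = 20.0
    blur_sigma: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.pm_intensity, self.cytosol_intensity, self.background) < 0:
            raise ValueError("intensities must be >= 0")
        if self.cell_radius >= min(self.image_size) / 2:
            raise ValueError("cell radius must be < half the image size")
        if self.cell_radius <= self.ring_width:
            raise ValueError("cell radius must exceed ring width")


def gen_cell_image(params: ImageParams) -> tuple[np.ndarray, dict]:
    """Render a synthetic cell and return (image, ground-truth sidecar).

    The cell is an annulus of intensity P (the plasma-membrane ring) at the
    cell radius, interior C (cytosol), exterior B (background), Gaussian
    blurred and with additive Gaussian noise. Ground truth is the noiseless
    relative F_PM = (P − B) / (C − B); if C == B the ratio is undefined and
    the sidecar flags it.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_size
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - params.cell_center[1], xx - params.cell_center[0])
    img = np.full((ny, nx), params.background, dtype=float)
    img[r <= params.cell_radius] = params.cytosol_intensity
    ring = np.abs(r - params.cell_radius) <= params.ring_width / 2.0
    img[ring] = params.pm_intensity
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    denom = params.cytosol_intensity - params.background
    undefined = denom == 0
    truth = math.nan if undefined else (params.pm_intensity - params.background) / denom
    sidecar = {
        "relative_f_pm": truth,
        "undefined": bool(undefined),
        "cell_center": list(params.cell_center),
        "cell_radius": params.cell_radius,
        "seed": params.seed,
    }
    return img, sidecar


# -------------------------------------------------------------------- kinetics

@dataclass
class AssayParams:
    """Ground truth for a real-time kinase assay simulation.

    ``vmax_true`` is the limiting initial velocity in product mol% per
    second; ``calibration_slope`` converts product mol% to fluorescence
    signal. Each progress curve plateaus when the substrate at that level is
    fully converted (product mol% capped at S).
    """

    vmax_true: float = 0.02          # mol% product / s
    khalf_true: float = 6.2          # mol% PI4P at half-maximal velocity
    hill_true: float = 2.0
    substrate_levels: tuple = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0)
    timepoints: tuple = tuple(range(0, 601))  # s, 1 Hz like the plate reader
    baseline_window: float = 30.0    # s of pre-ATP reads
    baseline: float = 100.0          # signal units
    noise_sigma: float = 0.0         # signal units
    background_drift: float = 0.0    # signal / s
    calibration_slope: float = 2000.0  # signal per mol% product
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if min(self.vmax_true, self.khalf_true, self.hill_true) <= 0:
            raise ValueError("kinetic parameters must be positive")
        if not self.substrate_levels:
            raise ValueError("substrate_levels must be non-empty")
        if len(set(self.substrate_levels)) != len(self.substrate_levels) or min(
            self.substrate_levels
        ) <= 0:
            raise ValueError("substrate levels must be distinct and positive")


def hill_velocity(S, vmax, khalf, h):
    """Allosteric sigmoidal velocity law v(S) = Vmax·S^h / (Khalf^h + S^h)."""
    S = np.asarray(S, dtype=float)
    return vmax * S ** h / (khalf ** h + S ** h)


@dataclass
class AssayRun:
    curves: list            # list of (S mol%, ProgressCurve)
    background: object      # ProgressCurve at 0 mol% substrate
    standards: pd.DataFrame  # probe calibration standards (mol_percent, signal)
    truth: dict


def gen_progress_curve_set(params: AssayParams) -> AssayRun:
    """Simulate progress curves at each substrate level plus background.

    signal(t) = baseline + drift·t + calibration_slope·min(v(S)·t, S) + noise;
    the matched background curve (0 mol% substrate) shares baseline and drift.
    """
    from .kinase_kinetics import ProgressCurve

    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.timepoints, dtype=float)
    n_base = max(int(params.baseline_window), 1)

    def make_curve(S: float) -> "ProgressCurve":
        v = hill_velocity(S, params.vmax_true, params.khalf_true, params.hill_true) if S > 0 else 0.0
        product = np.minimum(v * t, S) if S > 0 else np.zeros_like(t)
        sig = params.baseline + params.background_drift * t + params.calibration_slope * product
        sig = sig + rng.normal(0.0, params.noise_sigma, sig.shape) if params.noise_sigma else sig
        pre = params.baseline + (
            rng.normal(0.0, params.noise_sigma, n_base) if params.noise_sigma else 0.0
        )
        return ProgressCurve(
            time=t, signal=sig, baseline=float(np.mean(pre)),
            metadata={"substrate_mol_percent": S},
        )

    curves = []
    for S in params.substrate_levels:
        for _ in range(params.n_replicates):
            curves.append((S, make_curve(S)))
    background = make_curve(0.0)

    std_x = np.array([0.125, 0.25, 0.5, 1.0])
    std_y = params.calibration_slope * std_x + params.baseline
    std_y = std_y + (rng.normal(0.0, params.noise_sigma, std_y.shape) if params.noise_sigma else 0.0)
    standards = pd.DataFrame({"mol_percent": std_x, "signal": std_y})

    truth = {
        "vmax": params.vmax_true,
        "khalf": params.khalf_true,
        "hill": params.hill_true,
        "calibration_slope": params.calibration_slope,
    }
    return AssayRun(curves=curves, background=background, standards=standards, truth=truth)


# ---------------------------------------------------------------------- FRET

@dataclass
class SpectraParams:
    """Ground truth for three-channel spectral calibration series.

    ``a_true`` and ``b_true`` are the donor→FRET and acceptor→FRET
    bleed-through fractions; ``c_true`` a constant instrument offset.
    Defaults are the reference CFP/Venus coefficients (42.38% and 3.206%).
    """

    a_true: float = 0.4238
    b_true: float = 0.03206
    c_true: float = 0.0
    donor_levels: tuple = (2000.0, 5000.0, 10000.0, 20000.0, 40000.0)
    acceptor_levels: tuple = (2000.0, 5000.0, 10000.0, 20000.0, 40000.0)
    fret_component: float = 3000.0
    noise_sigma: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.a_true < 1 and 0 <= self.b_true < 1):
            raise ValueError("bleed-through fractions must be in [0, 1)")
        if min(self.donor_levels) < 0 or min(self.acceptor_levels) < 0:
            raise ValueError("levels must be non-negative")


def gen_calibration_spectra(params: SpectraParams) -> pd.DataFrame:
    """Donor-only, acceptor-only and mixed three-channel readings.

    Returns a table with columns ``sample_id, role, D, A, F``; the mixed
    samples carry the injected ``fret_component`` on top of bleed-through.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []

    def noise():
        return rng.normal(0.0, params.noise_sigma) if params.noise_sigma else 0.0

    i = 0
    for D in params.donor_levels:
        for _ in range(params.n_replicates):
            rows.append((f"d{i}", "donor_only", D, 0.0,
                         params.a_true * D + params.c_true + noise()))
            i += 1
    for A in params.acceptor_levels:
        for _ in range(params.n_replicates):
            rows.append((f"a{i}", "acceptor_only", 0.0, A,
                         params.b_true * A + params.c_true + noise()))
            i += 1
    for D, A in zip(params.donor_levels, params.acceptor_levels):
        for _ in range(params.n_replicates):
            F = (params.a_true * D + params.b_true * A + params.c_true
                 + params.fret_component + noise())
            rows.append((f"m{i}", "mixed", D, A, F))
            i += 1
    return pd.DataFrame(rows, columns=["sample_id", "role", "D", "A", "F"])
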