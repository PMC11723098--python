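"""Forward simulation of swept-source OCT interferograms.

A swept laser sweeps its wavelength across ``[lambda_min, lambda_max]``
while a Michelson interferometer mixes the reference arm (mirror at
optical path length ``d_r``, reflectivity ``r_r``) with backscatter from
sample scatterers at path lengths ``d_Si`` with reflectivities ``r_Si``.
The detected spectral intensity for one A-scan is

    I_D(k) = I1 + I2 + I3 + N_G,

where ``I2 = S(k) (rho/2) sum_i sqrt(r_r r_Si) cos(k (d_r - d_Si))`` is the
depth-encoding cross term, ``I1`` is the DC pedestal, ``I3`` the mutual
interference between scatterers, and ``N_G`` additive Gaussian noise.
``S(k)`` is the source spectral envelope; its inverse DFT is the axial
point-spread function, so a Gaussian source of bandwidth ``delta_lambda``
gives an axial FWHM of ``(4 ln2 / pi) lambda0^2 / delta_lambda`` in the
path-length coordinate (about 15 um for a 1310/100 nm source).

Depths are micrometres of optical path difference in air; wavelengths are
nanometres; wavenumbers ``k = 2 pi / lambda`` are rad/nm.

Speckle is produced physically: many sub-resolution scatterers at random
depths per resolution cell interfere coherently, so the reconstructed
magnitude is Rayleigh-distributed within a uniform layer (contrast
std/mean near 0.52).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

UM_TO_NM = 1e3

__all__ = [
    "SourceSpec", "SweepModel", "Phantom", "SimOptions", "RawFringeFrame",
    "sample_wavelength_grid", "source_envelope", "simulate_fringes",
    "make_speckle_phantom", "unambiguous_depth_um", "depth_pitch_um",
    "measure_psf_fwhm",
    "generate_dataset", "DatasetItem", "PairedDataset",
]


@dataclass(frozen=True)
class SourceSpec:
    """Swept-laser source: central wavelength, bandwidth, envelope shape."""

    lambda0: float = 1310.0       # nm
    delta_lambda: float = 100.0   # nm, FWHM of the spectral envelope
    shape: str = "gaussian"       # {"gaussian", "flat"}
    rho: float = 1.0              # detector responsivity (scale)

    def __post_init__(self):
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be positive")
        if not 0 < self.delta_lambda < self.lambda0:
            raise ValueError("require 0 < delta_lambda < lambda0")
        if self.shape not in ("gaussian", "flat"):
            raise ValueError(f"unknown envelope shape {self.shape!r}")


@dataclass(frozen=True)
class SweepModel:
    """How wavelength maps to the sample index during one sweep.

    kinds:
      * ``k_linear``        — wavenumber affine in sample index (ideal system)
      * ``lambda_linear``   — wavelength affine in time (plain swept source)
      * ``fdml_sinusoidal`` — wavelength sinusoidal in time, sampled over the
        monotonic up-sweep between the turning points (FDML laser whose
        Fabry-Perot filter is tuned at frequency ``f_t``)
    """

    kind: str
    n_samples: int
    lambda_min: float  # nm
    lambda_max: float  # nm
    beta: Optional[float] = None   # sweep speed, nm per unit time
    f_t: float = 1.0               # FP-filter tuning frequency, 1/time

    def __post_init__(self):
        if self.kind not in ("k_linear", "lambda_linear", "fdml_sinusoidal"):
            raise ValueError(f"unknown sweep kind {self.kind!r}")
        if not self.lambda_min < self.lambda_max:
            raise ValueError("require lambda_min < lambda_max")
        if self.n_samples < 2:
            raise ValueError("need at least 2 spectral samples")

    @property
    def lambda0(self) -> float:
        return 0.5 * (self.lambda_min + self.lambda_max)

    @property
    def delta_lambda_range(self) -> float:
        return self.lambda_max - self.lambda_min


@dataclass
class Phantom:
    """Scatterer configuration: the simulator's ground truth.

    ``scatterers[j]`` is an ``(n_j, 2)`` array of (depth um, reflectivity)
    for lateral position j.  ``d_r``/``r_r`` are the reference mirror's
    path length and reflectivity.
    """

    a_scans: int
    scatterers: list  # list of (n_j, 2) float arrays
    d_r: float = 0.0
    r_r: float = 1.0

    def __post_init__(self):
        if len(self.scatterers) != self.a_scans:
            raise ValueError("scatterers must have one entry per A-scan")
        self.scatterers = [np.atleast_2d(np.asarray(s, dtype=float)).reshape(-1, 2)
                           for s in self.scatterers]
        for s in self.scatterers:
            if s.size and (s[:, 1].min() < 0 or s[:, 1].max() > 1):
                raise ValueError("reflectivities must lie in [0, 1]")
            if s.size and s[:, 0].min() < 0:
                raise ValueError("depths must be >= 0")

    @classmethod
    def single_reflector(cls, a_scans: int, depth_um: float,
                         reflectivity: float = 0.5, d_r: float = 0.0,
                         r_r: float = 1.0) -> "Phantom":
        sc = [np.array([[depth_um, reflectivity]]) for _ in range(a_scans)]
        return cls(a_scans=a_scans, scatterers=sc, d_r=d_r, r_r=r_r)


@dataclass(frozen=True)
class SimOptions:
    """Noise terms and model-term toggles for the forward simulation."""

    noise_sigma: float = 0.0
    include_dc: bool = False       # I1 pedestal
    include_cross: bool = False    # I3 mutual-interference term
    fixed_pattern: Optional[np.ndarray] = None  # column-constant background
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class RawFringeFrame:
    """One B-scan of detected spectra: (n_samples rows x a_scans columns)."""

    data: np.ndarray
    sweep: SweepModel
    source: SourceSpec

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("fringe data must be 2D (spectral x lateral)")
        if self.data.shape[0] != self.sweep.n_samples:
            raise ValueError("row count must equal sweep.n_samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("fringe data must be finite")


# ---------------------------------------------------------------------------


def sample_wavelength_grid(sweep: SweepModel) -> np.ndarray:
    """Wavelengths (nm) at each of the N spectral samples of one sweep.

    * ``lambda_linear``: affine ramp lambda_min -> lambda_max.
    * ``k_linear``: k = 2 pi / lambda affine in the sample index.
    * ``fdml_sinusoidal``: lambda(t) = lambda0 + (dl/2) sin(2 pi f_t t)
      sampled uniformly in t over the monotonic up-sweep
      t in [-1/(4 f_t), +1/(4 f_t)].
    """
    n = sweep.n_samples
    if sweep.kind == "lambda_linear":
        lam = np.linspace(sweep.lambda_min, sweep.lambda_max, n)
    elif sweep.kind == "k_linear":
        k = np.linspace(2 * np.pi / sweep.lambda_min,
                        2 * np.pi / sweep.lambda_max, n)
        lam = 2 * np.pi / k
    else:  # fdml_sinusoidal
        t = np.linspace(-1.0 / (4 * sweep.f_t), 1.0 / (4 * sweep.f_t), n)
        lam = (sweep.lambda0
               + 0.5 * sweep.delta_lambda_range * np.sin(2 * np.pi * sweep.f_t * t))
    if np.any(np.diff(lam) <= 0):
        raise ValueError("wavelength sweep must be strictly increasing "
                         "over the sampled window")
    return lam


def source_envelope(source: SourceSpec, k: np.ndarray) -> np.ndarray:
    """Spectral envelope S(k): Gaussian with FWHM mapped from delta_lambda,
    or flat (=1) for analytic fringe tests."""
    if source.shape == "flat":
        return np.ones_like(k)
    k0 = 2 * np.pi / source.lambda0
    delta_k = 2 * np.pi * source.delta_lambda / source.lambda0 ** 2  # FWHM in k
    return np.exp(-4 * np.log(2) * ((k - k0) / delta_k) ** 2)


def depth_pitch_um(sweep: SweepModel) -> float:
    """Path-length increment per depth pixel after the inverse DFT.

    For a k-linear grid with per-sample step dk, DFT bin m maps to path
    difference d_m = 2 pi m / (N dk); the pitch is the m=1 value.  Non-linear
    sweeps share the same nominal pitch through their k endpoints.
    """
    k_span = 2 * np.pi / sweep.lambda_min - 2 * np.pi / sweep.lambda_max
    dk = k_span / (sweep.n_samples - 1)
    return 2 * np.pi / (sweep.n_samples * dk) / UM_TO_NM


def unambiguous_depth_um(sweep: SweepModel) -> float:
    """Maximum path difference before fringe aliasing: N/2 depth pixels."""
    return (sweep.n_samples / 2) * depth_pitch_um(sweep)


def simulate_fringes(phantom: Phantom, source: SourceSpec, sweep: SweepModel,
                     opts: SimOptions = SimOptions()) -> RawFringeFrame:
    """Simulate the detected spectra of one B-scan.

    Each column holds S(k(s)) (rho/2) sum_i sqrt(r_r r_Si)
    cos(k(s) (d_r - d_Si)) plus the optional DC and mutual-interference
    terms and additive Gaussian noise.  Deterministic given ``opts.seed``.
    """
    lam = sample_wavelength_grid(sweep)
    k = 2 * np.pi / lam                       # rad/nm, decreasing
    env = source_envelope(source, k)
    rho = source.rho
    zmax = unambiguous_depth_um(sweep)
    rng = np.random.default_rng(opts.seed)

    frame = np.zeros((sweep.n_samples, phantom.a_scans))
    for j, sc in enumerate(phantom.scatterers):
        if sc.size == 0:
            continue
        d_um, r = sc[:, 0], sc[:, 1]
        if np.any(np.abs(phantom.d_r - d_um) > zmax):
            raise ValueError(
                f"scatterer beyond the unambiguous depth range ({zmax:.1f} um)")
        opd_nm = (phantom.d_r - d_um) * UM_TO_NM
        amp = np.sqrt(phantom.r_r * r)
        col = np.cos(np.outer(k, opd_nm)) @ amp            # (N,)
        frame[:, j] = env * (rho / 2.0) * col
        if opts.include_dc:
            frame[:, j] += env * (rho / 4.0) * (phantom.r_r + r.sum())
        if opts.include_cross and len(d_um) > 1:
            dij = (d_um[:, None] - d_um[None, :]) * UM_TO_NM
            aij = np.sqrt(np.outer(r, r))
            np.fill_diagonal(aij, 0.0)
            # sum over ordered pairs n != m
            cross = np.einsum("sij,ij->s", np.cos(k[:, None, None] * dij), aij,
                              optimize=True)
            frame[:, j] += env * (rho / 2.0) * cross
    if opts.fixed_pattern is not None:
        fp = np.asarray(opts.fixed_pattern, dtype=float)
        if fp.shape != (sweep.n_samples,):
            raise ValueError("fixed_pattern length must equal n_samples")
        frame += fp[:, None]
    if opts.noise_sigma > 0:
        frame += rng.normal(0.0, opts.noise_sigma, frame.shape)
    return RawFringeFrame(data=frame, sweep=sweep, source=source)


def make_speckle_phantom(geometry: Sequence[dict], scatterer_density: float,
                         a_scans: int, seed: int = 0, d_r: float = 0.0,
                         r_r: float = 1.0,
                         depth_pitch: float = 10.0) -> Phantom:
    """Phantom with dense sub-resolution scatterers inside layered regions.

    ``geometry`` is a sequence of layers, each a dict with keys ``d0``/``d1``
    (depth interval, um) and optional ``reflectivity`` (mean scatterer
    reflectivity, default 0.25).  ``scatterer_density`` is the expected
    scatterer count per depth pixel per A-scan (``depth_pitch`` um/pixel);
    depths are uniform within the layer and reflectivities uniform in
    (0, 2*mean], so the coherent sum over a resolution cell develops fully
    random phase (speckle).  Reproducible by ``seed``.
    """
    if scatterer_density <= 0:
        raise ValueError("scatterer_density must be positive")
    rng = np.random.default_rng(seed)
    scatterers = []
    for _ in range(a_scans):
        parts = []
        for layer in geometry:
            d0, d1 = float(layer["d0"]), float(layer["d1"])
            if not d1 > d0:
                raise ValueError("layer requires d1 > d0")
            mean_r = float(layer.get("reflectivity", 0.25))
            n = rng.poisson(scatterer_density * (d1 - d0) / depth_pitch)
            if n == 0:
                continue
            d = rng.uniform(d0, d1, n)
            r = rng.uniform(0.0, min(2 * mean_r, 1.0), n)
            parts.append(np.column_stack([d, r]))
        scatterers.append(np.concatenate(parts, axis=0) if parts
                          else np.zeros((0, 2)))
    return Phantom(a_scans=a_scans, scatterers=scatterers, d_r=d_r, r_r=r_r)


def measure_psf_fwhm(frame: RawFringeFrame, column: int = 0,
                     upsample: int = 16) -> tuple:
    """FWHM (um of path difference) of the dominant |IDFT| peak of one
    column, via zero-padded (sinc-interpolated) inverse DFT.

    Returns ``(fwhm_um, peak_depth_um)``.  Intended for single-reflector
    frames, where the peak is the axial point-spread function.
    """
    n = frame.sweep.n_samples
    spec = np.concatenate([frame.data[:, column],
                           np.zeros((upsample - 1) * n)])
    z = np.abs(np.fft.ifft(spec))[: upsample * n // 2]
    pk = int(np.argmax(z))
    half = z[pk] / 2.0
    lo = pk
    while lo > 0 and z[lo] > half:
        lo -= 1
    hi = pk
    while hi < len(z) - 1 and z[hi] > half:
        hi += 1
    # sub-bin linear interpolation at the half-power crossings
    f_lo = lo + (half - z[lo]) / (z[lo + 1] - z[lo])
    f_hi = hi - 1 + (z[hi - 1] - half) / (z[hi - 1] - z[hi])
    pitch = depth_pitch_um(frame.sweep) / upsample
    return (f_hi - f_lo) * pitch, pk * pitch


# ---------------------------------------------------------------------------
# paired-dataset generation


@dataclass
class DatasetItem:
    degraded: "BScanImage"        # noqa: F821 - preprocess.BScanImage
    ground_truth: "BScanImage"    # noqa: F821
    raw: RawFringeFrame
    split: str
    phantom_seed: int


@dataclass
class PairedDataset:
    items: list
    config: dict
    seed: int

    def split(self, name: str):
        return [it for it in self.items if it.split == name]


def _split_counts(n: int, percentages) -> tuple:
    p_train, p_val, p_test = percentages
    if p_train + p_val + p_test != 100:
        raise ValueError("split percentages must sum to 100")
    n_train = int(n * p_train / 100)
    n_val = int(n * p_val / 100)
    return n_train, n_val, n - n_train - n_val


def generate_dataset(config: dict) -> PairedDataset:
    """Generate paired (degraded, ground-truth, raw) B-scans.

    For each phantom the degraded input is the preprocessed IDFT image of
    a wavelength-non-linear frame, and the ground truth is the average of
    ``n_avg`` (default 7) k-linear reconstructions with independently
    redrawn speckle of the same layer geometry — emulating the averaging
    of consecutive B-scans of a static sample.

    Required config keys: ``sweep_kind`` and either ``n_samples`` +
    ``a_scans`` or explicit ``phantoms``.  Optional: ``lambda_min``,
    ``lambda_max``, ``n_items``, ``geometry`` (layer template), ``density``,
    ``noise_sigma``, ``n_avg``, ``split`` (default (70, 20, 10)), ``seed``,
    ``hann`` (default True), ``background`` (default "none"), ``source``.
    """
    from . import preprocess
    from .baseline import average_bscans

    for key in ("sweep_kind",):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    if "phantoms" not in config and ("n_samples" not in config
                                     or "a_scans" not in config):
        raise ValueError("config must give the image size "
                         "(n_samples, a_scans) or explicit phantoms")

    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    lam_min = float(config.get("lambda_min", 1260.0))
    lam_max = float(config.get("lambda_max", 1360.0))
    n_avg = int(config.get("n_avg", 7))
    noise_sigma = float(config.get("noise_sigma", 0.0))
    use_hann = bool(config.get("hann", True))
    background = config.get("background", "none")
    source = config.get("source", SourceSpec(
        lambda0=0.5 * (lam_min + lam_max), delta_lambda=lam_max - lam_min))

    phantoms = config.get("phantoms")
    if phantoms is not None:
        n_items = len(phantoms)
        n_samples = int(config.get("n_samples", 0)) or None
        a_scans = phantoms[0].a_scans
        if n_samples is None:
            raise ValueError("config must give n_samples with explicit phantoms")
        def realization(i, j):  # explicit phantoms are deterministic
            return phantoms[i]
    else:
        n_items = int(config.get("n_items", 8))
        n_samples = int(config["n_samples"])
        a_scans = int(config["a_scans"])
        density = float(config.get("density", 2.0))
        geometry_template = config.get("geometry")
        zmax = unambiguous_depth_um(SweepModel(
            kind="k_linear", n_samples=n_samples,
            lambda_min=lam_min, lambda_max=lam_max))
        pitch = depth_pitch_um(SweepModel(
            kind="k_linear", n_samples=n_samples,
            lambda_min=lam_min, lambda_max=lam_max))
        item_seeds = rng.integers(0, 2 ** 31 - 1, size=n_items)

        def item_geometry(i):
            if geometry_template is not None:
                return geometry_template
            # random layered sample: 1-3 layers within the usable depth
            g_rng = np.random.default_rng(item_seeds[i])
            n_layers = int(g_rng.integers(1, 4))
            edges = np.sort(g_rng.uniform(0.1 * zmax, 0.85 * zmax, 2 * n_layers))
            return [{"d0": edges[2 * m], "d1": edges[2 * m + 1],
                     "reflectivity": float(g_rng.uniform(0.1, 0.45))}
                    for m in range(n_layers)]

        def realization(i, j):
            return make_speckle_phantom(
                item_geometry(i), density, a_scans,
                seed=int(item_seeds[i]) + 7919 * j, depth_pitch=pitch)

    sweep_degraded = SweepModel(kind=config["sweep_kind"], n_samples=n_samples,
                                lambda_min=lam_min, lambda_max=lam_max)
    sweep_klin = replace(sweep_degraded, kind="k_linear")

    def preprocess_frame(frame):
        if background == "mean_ascan":
            frame = preprocess.subtract_background(frame, "mean-a-scan")
        if use_hann:
            frame = preprocess.apply_hann(frame)
        return preprocess.fringes_to_image(frame)

    items = []
    n_train, n_val, n_test = _split_counts(n_items, tuple(config.get(
        "split", (70, 20, 10))))
    labels = (["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    order = rng.permutation(n_items)
    for rank, i in enumerate(order):
        opts0 = SimOptions(noise_sigma=noise_sigma, seed=seed + 31 * int(i))
        raw = simulate_fringes(realization(i, 0), source, sweep_degraded, opts0)
        degraded = preprocess_frame(raw)
        recons = []
        for j in range(n_avg):
            opts_j = SimOptions(noise_sigma=noise_sigma,
                                seed=seed + 31 * int(i) + 1000003 * j)
            fr = simulate_fringes(realization(i, j), source, sweep_klin, opts_j)
            recons.append(preprocess_frame(fr))
        gt = average_bscans(recons, n=n_avg)
        items.append(DatasetItem(degraded=degraded, ground_truth=gt, raw=raw,
                                 split=labels[rank], phantom_seed=int(i)))
    return PairedDataset(items=items, config=dict(config), seed=seed)
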