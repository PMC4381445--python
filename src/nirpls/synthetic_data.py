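"""Synthetic feedstock populations: composition, mixture spectra, reactivity.

The generator emulates the statistical structure of a multispecies
herbaceous-feedstock calibration study so that every pipeline stage can be
exercised end to end without measured data:

* composition (glucan, xylan, lignin, ash, wt% dry basis) drawn from
  truncated normals whose means/SDs/ranges match a broad six-feedstock
  population (glucan 33.2 +/- 6.3 wt% on [21.4, 47.8], etc.), with the
  remainder of the dry mass assigned to an unmodelled "other" fraction;
* absorbance spectra on the instrument grid (12,000-3,300 cm^-1 at
  3.857 cm^-1 spacing) built as Beer-Lambert mixtures of Gaussian-band
  pure-component bases, corrupted by per-sample multiplicative/additive
  scatter and per-replicate white noise, scanned in duplicate;
* sugar release generated as a linear function of composition (lignin
  entering negatively, reflecting recalcitrance) plus noise, targeting
  means/SDs of roughly 0.24 +/- 0.06 g/g (glucose) and 0.13 +/- 0.04 g/g
  (xylose); yields derived exactly by the release/yield arithmetic.

An optional two-component mixture per constituent is available for stress
tests, since real multispecies populations are rarely normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .reactivity_metrics import reactivity_table
from .spectra_io import ConstituentTable, SpectraMatrix

__all__ = [
    "SimConfig",
    "ConstituentParams",
    "Band",
    "sample_compositions",
    "make_basis_spectra",
    "generate_spectra",
    "generate_reactivity",
    "simulate_dataset",
]


@dataclass(frozen=True)
class ConstituentParams:
    """Truncated-normal parameters, wt% dry basis."""

    mean: float
    sd: float
    min: float
    max: float
    #: optional second mixture component (mean, sd, weight) for non-normal
    #: stress tests; None keeps a single truncated normal
    second_mode: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.min <= self.mean <= self.max:
            raise ValueError("need min <= mean <= max")


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: centre (cm^-1), width sigma (cm^-1),
    amplitude (absorbance per unit mass fraction)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("band width and amplitude must be > 0")


DEFAULT_CONSTITUENTS: dict[str, ConstituentParams] = {
    "glucan": ConstituentParams(33.2, 6.3, 21.4, 47.8),
    "xylan": ConstituentParams(17.8, 3.4, 9.5, 28.7),
    "lignin": ConstituentParams(15.2, 3.8, 6.7, 29.0),
    "ash": ConstituentParams(6.7, 3.6, 0.9, 16.4),
}

# Band positions sit mostly inside the modelled 4,000-8,998 cm^-1 window.
# The table is a stand-in for real O-H/C-H overtone structure, shaped so the
# inverse problem has realistic difficulty: the carbohydrate/water matrix
# (glucan and the unmodelled remainder) dominates total absorbance; xylan and
# lignin are weak signals buried under the glucan bands; ash — a mineral with
# essentially no NIR overtones — is nearly spectrally silent and predictable
# only indirectly.  With the default scatter and noise this places the
# cross-validated precision of a well-built model near the wt%-scale
# uncertainty typical of the reference wet chemistry (roughly 0.5-1 wt%),
# rather than at an unrealistically exact optimum.
DEFAULT_BANDS: dict[str, tuple[Band, ...]] = {
    "glucan": (Band(4400, 120, 3.2), Band(5200, 180, 5.2), Band(6300, 250, 2.9)),
    "xylan": (Band(4350, 110, 0.148), Band(5350, 170, 0.251), Band(6500, 240, 0.118)),
    "lignin": (Band(4430, 150, 0.333), Band(5260, 210, 0.435), Band(6380, 300, 0.218)),
    "ash": (Band(5050, 300, 0.049), Band(7100, 400, 0.061), Band(8000, 400, 0.031)),
    "other": (Band(4800, 300, 0.8), Band(6500, 400, 1.0), Band(9500, 500, 0.5)),
}

#: linear composition -> release coefficients (intercept, per-wt% slopes);
#: lignin enters negatively (recalcitrance)
DEFAULT_REACTIVITY_COEFFS: dict[str, dict[str, float]] = {
    "G.Release": {"intercept": 0.066, "glucan": 0.008, "lignin": -0.006},
    "X.Release": {"intercept": 0.046, "xylan": 0.009, "lignin": -0.005},
}
DEFAULT_REACTIVITY_NOISE_SD: dict[str, float] = {"G.Release": 0.02, "X.Release": 0.015}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator."""

    n_samples: int = 279
    seed: int = 0
    grid_lo: float = 3300.0
    grid_hi: float = 12000.0
    grid_spacing: float = 3.857
    constituent_params: dict[str, ConstituentParams] = field(
        default_factory=lambda: dict(DEFAULT_CONSTITUENTS))
    band_params: dict[str, tuple[Band, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    scatter_multiplicative_sd: float = 0.10
    scatter_additive_sd: float = 0.05
    noise_sd: float = 1e-3
    n_replicates: int = 2
    reactivity_coeffs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REACTIVITY_COEFFS.items()})
    reactivity_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REACTIVITY_NOISE_SD))

    def __post_init__(self):
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.grid_lo >= self.grid_hi:
            raise ValueError("grid_lo must be < grid_hi")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def wavenumbers(self) -> np.ndarray:
        """Decreasing instrument axis, values exact at 3 decimals."""
        n = int(np.floor((self.grid_hi - self.grid_lo) / self.grid_spacing)) + 1
        axis = self.grid_hi - self.grid_spacing * np.arange(n)
        return np.round(axis, 3)

    def constituent_names(self) -> list[str]:
        return list(self.constituent_params)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _truncnorm_draw(rng, params: ConstituentParams, size: int) -> np.ndarray:
    if params.sd == 0:
        return np.full(size, params.mean)
    a = (params.min - params.mean) / params.sd
    b = (params.max - params.mean) / params.sd
    return stats.truncnorm.rvs(a, b, loc=params.mean, scale=params.sd,
                               size=size, random_state=rng)


def sample_compositions(config: SimConfig) -> ConstituentTable:
    """Draw per-sample composition (wt% dry basis).

    Each constituent is an independent truncated normal (or two-component
    mixture when ``second_mode`` is set).  Rows whose constituents sum above
    100 wt% are redrawn so the implicit "other" fraction stays non-negative.
    """
    rng = config.rng(1)
    names = config.constituent_names()
    n = config.n_samples
    values = np.empty((n, len(names)))
    for j, name in enumerate(names):
        p = config.constituent_params[name]
        col = _truncnorm_draw(rng, p, n)
        if p.second_mode is not None:
            mean2, sd2, w2 = p.second_mode
            alt = _truncnorm_draw(rng, replace(p, mean=mean2, sd=sd2, second_mode=None), n)
            pick = rng.random(n) < w2
            col = np.where(pick, alt, col)
        values[:, j] = col
    # reject rows exceeding 100 wt% total (other fraction must be >= 0)
    for _ in range(1000):
        bad = values.sum(axis=1) > 100.0
        if not bad.any():
            break
        for j, name in enumerate(names):
            values[bad, j] = _truncnorm_draw(rng, config.constituent_params[name],
                                             int(bad.sum()))
    else:
        raise ValueError("infeasible composition bounds: totals always exceed 100 wt%")
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return ConstituentTable(ids, names, values, {n_: "wt%_dry" for n_ in names})


def make_basis_spectra(config: SimConfig) -> dict[str, np.ndarray]:
    """Pure-component basis spectra (sum of Gaussian bands) on the grid.

    Includes the constituents plus the ``other`` (unmodelled remainder)
    basis.  Raises if the bases are numerically collinear.
    """
    nu = config.wavenumbers()
    basis: dict[str, np.ndarray] = {}
    for name, bands in config.band_params.items():
        for band in bands:
            if not (min(config.grid_lo, config.grid_hi) <= band.center
                    <= max(config.grid_lo, config.grid_hi)):
                raise ValueError(f"band centre {band.center} outside grid for {name!r}")
        s = np.zeros_like(nu)
        for band in bands:
            s += band.amplitude * np.exp(-0.5 * ((nu - band.center) / band.width) ** 2)
        basis[name] = s
    M = np.column_stack(list(basis.values()))
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[-1] <= 1e-6 * sv[0] or sv[-1] <= 1e-6:
        raise ValueError("degenerate (collinear) pure-component bases")
    return basis


def generate_spectra(
    compositions: ConstituentTable,
    basis: dict[str, np.ndarray],
    config: SimConfig,
) -> SpectraMatrix:
    """Beer-Lambert mixture spectra with scatter and noise, in duplicate.

    spectrum = a_i * (sum_k c_ik basis_k) + b_i + eps, with the scatter
    coefficients a_i ~ 1 + N(0, mult sd) and offset b_i ~ N(0, add sd) drawn
    per physical sample and the white noise eps per replicate scan.
    """
    rng = config.rng(2)
    nu = config.wavenumbers()
    names = compositions.constituent_names
    for name in names:
        if name not in basis:
            raise ValueError(f"no basis spectrum for constituent {name!r}")
    C = compositions.values / 100.0  # wt% -> mass fraction
    B = np.vstack([basis[n] for n in names])
    mix = C @ B
    if "other" in basis:
        other = 1.0 - C.sum(axis=1)
        mix = mix + np.outer(other, basis["other"])
    n = mix.shape[0]
    a = 1.0 + rng.normal(0.0, config.scatter_multiplicative_sd, size=n)
    b = rng.normal(0.0, config.scatter_additive_sd, size=n)
    ids: list[str] = []
    rows = np.empty((n * config.n_replicates, nu.size))
    k = 0
    for i, sid in enumerate(compositions.sample_ids):
        clean = a[i] * mix[i] + b[i]
        for r in range(config.n_replicates):
            eps = rng.normal(0.0, config.noise_sd, size=nu.size) if config.noise_sd > 0 else 0.0
            rows[k] = clean + eps
            ids.append(f"{sid}_rep{r + 1}" if config.n_replicates > 1 else sid)
            k += 1
    return SpectraMatrix(ids, nu, rows)


def generate_reactivity(compositions: ConstituentTable, config: SimConfig) -> ConstituentTable:
    """Release drawn linearly from composition (plus noise, clipped >= 0);
    yields computed exactly from the simulated releases."""
    rng = config.rng(3)
    n = compositions.n_samples
    releases: dict[str, np.ndarray] = {}
    for target in ("G.Release", "X.Release"):
        coeffs = config.reactivity_coeffs[target]
        y = np.full(n, coeffs.get("intercept", 0.0))
        for name, slope in coeffs.items():
            if name == "intercept":
                continue
            y = y + slope * compositions.column(name)
        sd = config.reactivity_noise_sd.get(target, 0.0)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=n)
        releases[target] = np.clip(y, 0.0, None)
    table = reactivity_table(
        releases["G.Release"], releases["X.Release"],
        glucan_frac=compositions.column("glucan") / 100.0,
        xylan_frac=compositions.column("xylan") / 100.0,
    )
    names = list(table)
    values = np.column_stack([table[n_] for n_ in names])
    units = {n_: ("g_per_g" if "Release" in n_ else "fraction") for n_ in names}
    return ConstituentTable(list(compositions.sample_ids), names, values, units)


def simulate_dataset(config: SimConfig):
    """Full synthetic study: (duplicate-scan spectra, composition, reactivity)."""
    compositions = sample_compositions(config)
    basis = make_basis_spectra(config)
    spectra = generate_spectra(compositions, basis, config)
    reactivity = generate_reactivity(compositions, config)
    return spectra, compositions, reactivity
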