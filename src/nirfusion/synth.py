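"""Synthetic lab panels and linked FT-NIR spectra.

Generates per-fruit quality panels (SSC, titratable acidity, vitamin C,
anthocyanins, phenolic acids) for a set of cultivars, and absorbance
spectra whose Gaussian band amplitudes are linked to the panel values,
plus multiplicative/additive scatter, instrument noise and
missing-at-random lab records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LAB_PARAMS",
    "CultivarProfile",
    "LabPanel",
    "SpectraBlock",
    "Band",
    "BandModel",
    "DEFAULT_GRID",
    "default_profiles",
    "default_band_model",
    "generate_lab_panel",
    "generate_spectra",
    "inject_missing",
]

#: Canonical order of the five lab parameters.
LAB_PARAMS = ("ssc", "ta", "vitamin_c", "anthocyanins", "phenolic_acids")

#: Instrument grid: 10,000 -> 4,000 cm-1, 1557 points, descending.
DEFAULT_GRID = (10_000.0, 4_000.0, 1557)


def _default_cvs() -> np.ndarray:
    # 0.12 is typical fruit-to-fruit variability; vitamin C is wider so the
    # printed letter groupings stay recoverable at n = 54 per cultivar
    return np.array([0.12, 0.12, 0.25, 0.12, 0.12])


def _default_corr() -> np.ndarray:
    corr = np.eye(5)
    corr[0, 1] = corr[1, 0] = 0.4   # SSC - TA
    corr[3, 4] = corr[4, 3] = 0.3   # anthocyanins - phenolic acids
    return corr


@dataclass(frozen=True)
class CultivarProfile:
    """Generator parameters for one cultivar.

    ``lab_means`` follows :data:`LAB_PARAMS` order; ``lab_cvs`` are
    coefficients of variation (sd = cv * mean); ``lab_corr`` is the
    within-cultivar correlation matrix of the five parameters.
    ``band_links`` optionally overrides the band model's amplitude links
    for fruits of this cultivar.
    """

    name: str
    lab_means: np.ndarray
    lab_cvs: np.ndarray = field(default_factory=_default_cvs)
    lab_corr: np.ndarray = field(default_factory=_default_corr)
    band_links: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "lab_means", np.asarray(self.lab_means, float))
        object.__setattr__(self, "lab_cvs", np.asarray(self.lab_cvs, float))
        object.__setattr__(self, "lab_corr", np.asarray(self.lab_corr, float))
        if self.lab_means.shape != (5,) or np.any(self.lab_means <= 0):
            raise ValueError(f"{self.name}: lab_means must be 5 strictly positive values")
        if np.any(self.lab_cvs < 0):
            raise ValueError(f"{self.name}: lab_cvs must be non-negative")
        c = self.lab_corr
        if c.shape != (5, 5) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError(f"{self.name}: lab_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError(f"{self.name}: lab_corr is not positive semi-definite")

    @property
    def lab_sds(self) -> np.ndarray:
        return self.lab_cvs * self.lab_means

    @property
    def covariance(self) -> np.ndarray:
        d = np.diag(self.lab_sds)
        return d @ self.lab_corr @ d


def default_profiles() -> list[CultivarProfile]:
    """The four default cultivars (means in LAB_PARAMS order)."""
    means = {
        "Cristina": [7.38, 0.68, 14.31, 38.98, 19.16],
        "Romina": [6.15, 0.48, 31.84, 93.81, 21.03],
        "Sibilla": [7.66, 0.75, 31.33, 48.98, 31.35],
        "Silvia": [4.83, 0.65, 15.64, 61.00, 29.17],
    }
    return [CultivarProfile(name=k, lab_means=v) for k, v in means.items()]


@dataclass
class LabPanel:
    """Per-fruit lab quality panel (one row per fruit)."""

    sample_id: np.ndarray          # str array, unique per fruit
    cultivar: np.ndarray           # str array
    harvest: np.ndarray            # int array in {1, 2}
    values: np.ndarray             # (n_fruits, 5) float
    missing_mask: np.ndarray       # (n_fruits, 5) bool; True = missing

    def __post_init__(self):
        n = len(self.sample_id)
        if self.values.shape != (n, 5) or self.missing_mask.shape != (n, 5):
            raise ValueError("panel arrays are inconsistent")
        if len(np.unique(self.sample_id)) != n:
            raise ValueError("sample_id values must be unique (one row per fruit)")
        present = ~self.missing_mask
        if np.any(self.values[present] < 0):
            raise ValueError("present lab values must be non-negative")

    @property
    def n_fruits(self) -> int:
        return len(self.sample_id)

    def complete_case_mask(self) -> np.ndarray:
        return ~self.missing_mask.any(axis=1)

    def complete_cases(self) -> "LabPanel":
        keep = self.complete_case_mask()
        return LabPanel(
            sample_id=self.sample_id[keep],
            cultivar=self.cultivar[keep],
            harvest=self.harvest[keep],
            values=self.values[keep],
            missing_mask=self.missing_mask[keep],
        )

    def copy(self) -> "LabPanel":
        return LabPanel(
            sample_id=self.sample_id.copy(),
            cultivar=self.cultivar.copy(),
            harvest=self.harvest.copy(),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
        )


@dataclass
class SpectraBlock:
    """Observations x wavenumbers absorbance matrix with row labels."""

    grid: np.ndarray               # wavenumbers, cm-1, strictly monotone
    X: np.ndarray                  # (n_obs, n_wavenumbers)
    sample_id: np.ndarray
    cultivar: np.ndarray
    replicate: np.ndarray          # int, 1-based

    def __post_init__(self):
        if self.X.shape[1] != len(self.grid):
            raise ValueError(
                f"grid length {len(self.grid)} != number of columns {self.X.shape[1]}"
            )
        if self.X.shape[0] != len(self.sample_id):
            raise ValueError("row label length mismatch")
        d = np.diff(self.grid)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("grid must be strictly monotone")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("absorbances must be finite")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return len(np.unique(self.sample_id))

    def copy(self) -> "SpectraBlock":
        return SpectraBlock(
            grid=self.grid.copy(),
            X=self.X.copy(),
            sample_id=self.sample_id.copy(),
            cultivar=self.cultivar.copy(),
            replicate=self.replicate.copy(),
        )


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``links`` maps lab parameter names (or the latent ``"water"`` term)
    to amplitude coefficients: amplitude = base_amplitude + sum(link * value).
    """

    center: float                  # cm-1
    width: float                   # Gaussian sigma, cm-1
    base_amplitude: float
    links: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BandModel:
    """Bands plus a broad water baseline.

    ``cultivar_links`` optionally overrides a band's link mapping for the
    fruits of one cultivar: ``{cultivar: {band_center: {param: coef}}}``.
    An override replaces that band's links entirely for that cultivar.
    """

    bands: tuple[Band, ...]
    baseline_offset: float = 0.15
    baseline_center: float = 5100.0
    baseline_width: float = 1400.0
    baseline_amplitude: float = 0.6
    water_latent_sd: float = 0.05   # latent water term ~ N(1, sd) per fruit
    cultivar_links: dict = field(default_factory=dict)


def default_band_model(link_scale: float = 1.0, pair_contrast: float = 1.0) -> BandModel:
    """Default three-band model on a broad water baseline.

    The 6860 cm-1 band is positively linked to SSC and TA, the
    5188 cm-1 band to the per-fruit latent water term, and the
    8580 cm-1 band (CH second-overtone region) carries a weak
    vitamin C link.  ``link_scale`` multiplies every composition link.
    ``pair_contrast`` multiplies the vitamin-C coefficient for the
    high-vitamin-C cultivar pair (Romina, Sibilla) only, raising the
    spectral contrast between the two cultivar pairs without inflating
    within-cultivar spread; 1.0 means no contrast (uniform links).
    """
    s = float(link_scale)
    vitc = 0.004 * s
    cultivar_links = {}
    if pair_contrast != 1.0:
        boosted = {8580.0: {"vitamin_c": vitc * float(pair_contrast)}}
        cultivar_links = {"Romina": boosted, "Sibilla": boosted}
    return BandModel(
        bands=(
            Band(5188.0, 180.0, 0.55, {"water": 0.25 * s}),
            Band(6860.0, 220.0, 0.10, {"ssc": 0.020 * s, "ta": 0.080 * s}),
            Band(8580.0, 260.0, 0.08, {"vitamin_c": vitc}),
        ),
        cultivar_links=cultivar_links,
    )


def _truncated_mvnormal(rng: np.random.Generator, mean, cov, n: int) -> np.ndarray:
    """Draw n vectors from N(mean, cov) conditioned on all coordinates >= 0.

    Truncation by resampling keeps the mean essentially unbiased for
    moderate coefficients of variation (cv <= 0.3).
    """
    out = rng.multivariate_normal(mean, cov, size=n, method="svd")
    bad = np.where((out < 0).any(axis=1))[0]
    tries = 0
    while bad.size:
        out[bad] = rng.multivariate_normal(mean, cov, size=bad.size, method="svd")
        bad = np.where((out < 0).any(axis=1))[0]
        tries += 1
        if tries > 1000:
            raise RuntimeError("zero-truncation resampling did not converge")
    return out


def generate_lab_panel(
    profiles: list[CultivarProfile],
    n_per_cultivar: int,
    seed: int,
) -> LabPanel:
    """Draw ``n_per_cultivar`` fruits per cultivar from each profile's
    zero-truncated multivariate normal.  Fruits are emitted in cultivar
    blocks; the first half of each block is tagged harvest 1, the rest
    harvest 2.
    """
    if n_per_cultivar < 1:
        raise ValueError("n_per_cultivar must be >= 1")
    if not profiles:
        raise ValueError("profiles must be non-empty")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("profile names must be distinct")

    rng = np.random.default_rng(seed)
    ids, cults, harvests, vals = [], [], [], []
    for p in profiles:
        v = _truncated_mvnormal(rng, p.lab_means, p.covariance, n_per_cultivar)
        vals.append(v)
        ids.extend(f"{p.name}-{i + 1:03d}" for i in range(n_per_cultivar))
        cults.extend([p.name] * n_per_cultivar)
        half = n_per_cultivar // 2
        harvests.extend([1] * half + [2] * (n_per_cultivar - half))
    values = np.vstack(vals)
    return LabPanel(
        sample_id=np.array(ids),
        cultivar=np.array(cults),
        harvest=np.array(harvests, int),
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
    )


def _gauss(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def generate_spectra(
    panel: LabPanel,
    grid_spec: tuple[float, float, int] = DEFAULT_GRID,
    band_model: BandModel | None = None,
    scatter: tuple[float, float] = (0.02, 0.01),
    noise_sd: float = 0.002,
    seed: int = 0,
    n_replicates: int = 2,
) -> SpectraBlock:
    """Simulate ``n_replicates`` absorbance spectra per fruit.

    Each fruit's noiseless spectrum is a baseline plus Gaussian bands
    whose amplitudes are affine in the fruit's lab values (and a latent
    water term); every observation then gets its own multiplicative and
    additive scatter draw and iid noise — the replicate effect is
    scatter-only, the composition signal is shared.
    """
    if band_model is None:
        band_model = default_band_model()
    start, end, n_points = grid_spec
    if n_points < 2:
        raise ValueError("grid must have at least 2 points")
    grid = np.linspace(start, end, int(n_points))
    lo, hi = min(start, end), max(start, end)

    param_index = {p: i for i, p in enumerate(LAB_PARAMS)}

    # validate band-linked values are present
    linked_params = set()
    for b in band_model.bands:
        linked_params.update(k for k in b.links if k != "water")
    for overrides in band_model.cultivar_links.values():
        for link_map in overrides.values():
            linked_params.update(k for k in link_map if k != "water")
    for k in linked_params:
        j = param_index[k]
        bad = np.where(panel.missing_mask[:, j])[0]
        if bad.size:
            raise ValueError(
                f"fruit {panel.sample_id[bad[0]]!r} is missing band-linked "
                f"lab value {k!r}; cannot simulate its spectrum"
            )

    rng = np.random.default_rng(seed)
    n = panel.n_fruits
    water = 1.0 + band_model.water_latent_sd * rng.standard_normal(n)

    base = np.zeros((n, len(grid)))
    base += band_model.baseline_offset
    base += band_model.baseline_amplitude * _gauss(
        grid, band_model.baseline_center, band_model.baseline_width
    )[None, :]
    for b in band_model.bands:
        if not (lo <= b.center <= hi):
            warnings.warn(
                f"band center {b.center} cm-1 outside grid [{lo}, {hi}]; skipped",
                stacklevel=2,
            )
            continue
        amp = np.full(n, b.base_amplitude)
        params = set(b.links)
        for overrides in band_model.cultivar_links.values():
            params |= set(overrides.get(b.center, {}))
        for key in sorted(params):
            coef = np.full(n, b.links.get(key, 0.0))
            for cname, overrides in band_model.cultivar_links.items():
                if b.center in overrides:
                    coef[panel.cultivar == cname] = overrides[b.center].get(key, 0.0)
            vals = water if key == "water" else panel.values[:, param_index[key]]
            amp = amp + coef * vals
        base += amp[:, None] * _gauss(grid, b.center, b.width)[None, :]

    mult_sd, add_sd = scatter
    n_obs = n * n_replicates
    m = mult_sd * rng.standard_normal(n_obs)
    a = add_sd * rng.standard_normal(n_obs)
    noise = noise_sd * rng.standard_normal((n_obs, len(grid)))

    X = np.repeat(base, n_replicates, axis=0)
    X = (1.0 + m)[:, None] * X + a[:, None] + noise
    return SpectraBlock(
        grid=grid,
        X=X,
        sample_id=np.repeat(panel.sample_id, n_replicates),
        cultivar=np.repeat(panel.cultivar, n_replicates),
        replicate=np.tile(np.arange(1, n_replicates + 1), n),
    )


def inject_missing(panel: LabPanel, n_missing_fruits: int, seed: int) -> LabPanel:
    """Mask at least one lab value in exactly ``n_missing_fruits`` fruits,
    chosen uniformly at random (MCAR); other rows are untouched."""
    if n_missing_fruits < 0:
        raise ValueError("n_missing_fruits must be non-negative")
    if n_missing_fruits > panel.n_fruits:
        raise ValueError(
            f"n_missing_fruits={n_missing_fruits} exceeds panel size {panel.n_fruits}"
        )
    out = panel.copy()
    if n_missing_fruits == 0:
        return out
    rng = np.random.default_rng(seed)
    rows = rng.choice(panel.n_fruits, size=n_missing_fruits, replace=False)
    cols = rng.integers(0, 5, size=n_missing_fruits)
    out.missing_mask[rows, cols] = True
    return out
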