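"""Simulated-spectra corpus: sampling, noise, splits and scaling.

The working wavelength grid mirrors the camera convention: 299 bands evenly
spaced over 400-1000 nm, of which the 205 bands falling in [420, 830] nm are
retained for analysis (shorter and longer wavelengths carry too little
signal with a halogen source).

A corpus holds N reflectance spectra on that grid with paired labels
(log10 B, S, fm, a) exactly as the inverse network consumes them, additive
Gaussian noise with per-spectrum standard deviations drawn to hit a target
signal-to-noise ratio uniform in 10-16 dB (SNR defined on the mean squared
reflectance of the clean spectrum), and a random 64/16/20 train/val/test
partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tissue import TissueParams

__all__ = [
    "SamplingRanges",
    "ParamSample",
    "SpectraCorpus",
    "ScalerPair",
    "default_ranges",
    "sample_params",
    "make_band_grid",
    "add_noise",
    "split_corpus",
    "fit_scalers",
    "simulate_corpus",
]

SPLIT_NAMES = ("train", "val", "test")
SPLIT_FRACTIONS = (0.64, 0.16, 0.20)
SNR_RANGE_DB = (10.0, 16.0)


@dataclass(frozen=True)
class SamplingRanges:
    """Per-parameter (low, high, scale) bounds for corpus sampling."""

    B: tuple = (0.001, 0.10, "log")
    S: tuple = (0.0, 1.0, "linear")
    fm: tuple = (0.0, 0.20, "linear")
    a: tuple = (0.5, 5.0, "linear")

    def __post_init__(self):
        for name in ("B", "S", "fm", "a"):
            lo, hi, scale = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: low must be < high")
            if scale not in ("linear", "log"):
                raise ValueError(f"{name}: scale must be linear|log")
            if scale == "log" and lo <= 0:
                raise ValueError(f"{name}: log scale requires low > 0")

    def items(self):
        return [(n, getattr(self, n)) for n in ("B", "S", "fm", "a")]


def default_ranges() -> SamplingRanges:
    """Physiological defaults: B log-uniform 0.1-10%, S 0-100%, fm 0-20%,
    a 0.5-5 mm^-1."""
    return SamplingRanges()


@dataclass(frozen=True)
class ParamSample:
    """Columns of sampled tissue parameters."""

    B: np.ndarray
    S: np.ndarray
    fm: np.ndarray
    a: np.ndarray

    def __len__(self):
        return self.B.size

    def __getitem__(self, i) -> TissueParams:
        return TissueParams(
            float(self.B[i]), float(self.S[i]), float(self.fm[i]), float(self.a[i])
        )

    @property
    def labels(self) -> np.ndarray:
        """(N, 4) label matrix (log10 B, S, fm, a)."""
        return np.column_stack([np.log10(self.B), self.S, self.fm, self.a])


def sample_params(ranges: SamplingRanges, n: int, seed: int = 0) -> ParamSample:
    """Independent uniform draws per parameter on its declared scale."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cols = {}
    for name, (lo, hi, scale) in ranges.items():
        if scale == "log":
            cols[name] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), n)
        else:
            cols[name] = rng.uniform(lo, hi, n)
    return ParamSample(**cols)


def make_band_grid(
    n_bands: int = 299,
    full_range_nm: tuple[float, float] = (400.0, 1000.0),
    window_nm: tuple[float, float] = (420.0, 830.0),
) -> np.ndarray:
    """Retained camera band centers.

    Bands are lambda_i = 400 + i*(600/299) nm for i = 0..298; bands with
    420 <= lambda <= 830 nm are retained (205 of them with the defaults).
    """
    lo, hi = full_range_nm
    full = lo + np.arange(n_bands) * (hi - lo) / n_bands
    keep = (full >= window_nm[0]) & (full <= window_nm[1])
    return full[keep]


def add_noise(
    spectra: np.ndarray,
    snr_range_db: tuple[float, float] = SNR_RANGE_DB,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive i.i.d. Gaussian noise at a per-spectrum uniform target SNR.

    The target SNR (dB) is drawn uniformly per spectrum and sigma is set so
    that 10*log10(mean(Rd^2)/sigma^2) equals the drawn value.  Returns
    (noisy spectra, sigma per spectrum).
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.size == 0:
        raise ValueError("empty spectra")
    lo, hi = snr_range_db
    if not (lo > 0 and lo < hi):
        raise ValueError("snr bounds must be positive with low < high")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    snr = rng.uniform(lo, hi, spectra.shape[0])
    power = np.mean(spectra**2, axis=1)
    sigma = np.sqrt(power / 10.0 ** (snr / 10.0))
    noisy = spectra + rng.standard_normal(spectra.shape) * sigma[:, None]
    return noisy, sigma


@dataclass
class SpectraCorpus:
    """Labelled reflectance spectra with noise metadata and split tags."""

    wavelengths: np.ndarray          # (n_wl,)
    spectra: np.ndarray              # (N, n_wl) noisy reflectance
    labels: np.ndarray               # (N, 4): log10B, S, fm, a
    sigma: np.ndarray                # (N,) injected noise std
    split: np.ndarray                # (N,) int8: 0 train, 1 val, 2 test
    tissue: str = ""
    clean_spectra: np.ndarray | None = None

    label_names = ("log10B", "S", "fm", "a")

    def __post_init__(self):
        n = self.spectra.shape[0]
        if not (self.labels.shape == (n, 4) and self.sigma.shape == (n,)
                and self.split.shape == (n,)):
            raise ValueError("inconsistent corpus arrays")

    def __len__(self):
        return self.spectra.shape[0]

    def mask(self, split: str) -> np.ndarray:
        return self.split == SPLIT_NAMES.index(split)

    def subset(self, split: str) -> "SpectraCorpus":
        m = self.mask(split)
        return replace(
            self,
            spectra=self.spectra[m],
            labels=self.labels[m],
            sigma=self.sigma[m],
            split=self.split[m],
            clean_spectra=None if self.clean_spectra is None
            else self.clean_spectra[m],
        )

    def params(self, split: str | None = None) -> ParamSample:
        lab = self.labels if split is None else self.labels[self.mask(split)]
        return ParamSample(10.0 ** lab[:, 0], lab[:, 1], lab[:, 2], lab[:, 3])

    def save(self, path):
        np.savez_compressed(
            path, wavelengths=self.wavelengths, spectra=self.spectra,
            labels=self.labels, sigma=self.sigma, split=self.split,
            tissue=np.array(self.tissue),
            **({} if self.clean_spectra is None
               else {"clean_spectra": self.clean_spectra}),
        )

    @classmethod
    def load(cls, path) -> "SpectraCorpus":
        with np.load(path) as z:
            return cls(
                z["wavelengths"], z["spectra"], z["labels"], z["sigma"],
                z["split"], str(z["tissue"]),
                z["clean_spectra"] if "clean_spectra" in z else None,
            )


def split_corpus(n_or_corpus, seed: int = 0):
    """Random 64/16/20 train/val/test partition.

    Validation and test sizes are rounded down; the remainder goes to the
    training split (30,000 rows give 19,200 / 4,800 / 6,000).  Accepts a row
    count (returns the int8 tag vector) or a corpus (returns it re-tagged).
    """
    corpus = None
    if isinstance(n_or_corpus, SpectraCorpus):
        corpus = n_or_corpus
        n = len(corpus)
    else:
        n = int(n_or_corpus)
    if n < 3:
        raise ValueError("need at least 3 rows to split")
    n_val = int(np.floor(SPLIT_FRACTIONS[1] * n))
    n_test = int(np.floor(SPLIT_FRACTIONS[2] * n))
    n_train = n - n_val - n_test
    tags = np.concatenate(
        [np.zeros(n_train, np.int8), np.ones(n_val, np.int8),
         np.full(n_test, 2, np.int8)]
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rng.shuffle(tags)
    if corpus is None:
        return tags
    corpus.split = tags
    return corpus


@dataclass(frozen=True)
class ScalerPair:
    """Min-max scalers for spectra (per band) and labels (per column).

    Fitted on the training split only; transforms map the training min/max
    to [0, 1] without clipping, and a degenerate column (max == min) maps
    to 0 by convention.
    """

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: np.ndarray
    y_max: np.ndarray

    @staticmethod
    def _scale(v, lo, hi):
        span = np.where(hi > lo, hi - lo, 1.0)
        return np.where(hi > lo, (v - lo) / span, 0.0)

    @staticmethod
    def _unscale(v, lo, hi):
        return lo + v * np.where(hi > lo, hi - lo, 0.0)

    def transform_spectra(self, x):
        return self._scale(np.asarray(x, float), self.x_min, self.x_max)

    def inverse_spectra(self, x):
        return self._unscale(np.asarray(x, float), self.x_min, self.x_max)

    def transform_labels(self, y):
        return self._scale(np.asarray(y, float), self.y_min, self.y_max)

    def inverse_labels(self, y):
        return self._unscale(np.asarray(y, float), self.y_min, self.y_max)

    def to_dict(self):
        return {k: getattr(self, k).tolist()
                for k in ("x_min", "x_max", "y_min", "y_max")}

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: np.asarray(v, float) for k, v in d.items()})


def fit_scalers(corpus: SpectraCorpus) -> ScalerPair:
    """Fit per-band and per-label min-max scalers on the training split."""
    m = corpus.mask("train")
    if not m.any():
        raise ValueError("training split is empty")
    x = corpus.spectra[m]
    y = corpus.labels[m]
    return ScalerPair(x.min(0), x.max(0), y.min(0), y.max(0))


def simulate_corpus(
    forward,
    ranges: SamplingRanges | None = None,
    n: int = 30_000,
    seed: int = 0,
    snr_range_db: tuple[float, float] = SNR_RANGE_DB,
    tissue: str = "",
    keep_clean: bool = True,
) -> SpectraCorpus:
    """Sample parameters, forward-model spectra, add noise and split.

    ``forward`` is anything with a ``spectra(B, S, fm, a)`` method (an
    :class:`~hsiq.mc.RdLookup` or white-MC engine wrapper) plus a
    ``wavelengths`` attribute.
    """
    ranges = ranges or default_ranges()
    s0, s1, s2 = (int(s) for s in np.random.SeedSequence(seed).generate_state(3))
    p = sample_params(ranges, n, seed=s0)
    clean = forward.spectra(p.B, p.S, p.fm, p.a)
    noisy, sigma = add_noise(clean, snr_range_db, seed=s1)
    tags = split_corpus(n, seed=s2)
    return SpectraCorpus(
        wavelengths=np.asarray(forward.wavelengths, float).copy(),
        spectra=noisy, labels=p.labels, sigma=sigma, split=tags,
        tissue=tissue, clean_spectra=clean if keep_clean else None,
    )
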