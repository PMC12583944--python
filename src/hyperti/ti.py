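"""Total interdependence (TI) from epoch-averaged coherence, with a
permutation-null normalization.

TI measures the frequency-domain dependence between two signals by
integrating a log-transform of their magnitude-squared coherence over a band:

    TI(band) = - sum_{f in band} ln(1 - C(f))

with C(f) estimated Welch-style over 1-second epochs (linear detrend + Hann
window + DFT), so bins fall on integer hertz. TI is nonnegative and additive
over disjoint bands, but its raw value grows with the number of epochs
available (the coherence estimate is biased upward by ~1/K for K epochs), so
communications of different durations are not comparable on the raw scale.
Normalization fixes this: the pairing of one subject's epochs against the
other's is permuted many times (default 1000), TI is recomputed for each
permutation, and the observed TI is expressed as a z-score against that null.
A Lilliefors-type Kolmogorov-Smirnov audit flags nulls that depart from
normality, where the z-scale is less trustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "BandSpec",
    "ALL_BAND",
    "ALPHA_BAND",
    "DEFAULT_BANDS",
    "CoherenceSpectrum",
    "NullDistribution",
    "TIResult",
    "epoch_spectra",
    "coherence_epochs",
    "band_ti",
    "permutation_null",
    "nulls_from_spectra",
    "normalize_ti",
    "normalized_ti",
    "normalized_ti_from_spectra",
]

#: Guard against log divergence at perfect coherence (e.g. self-coherence).
COHERENCE_CLIP = 1.0 - 1e-10
#: Minimum permutations accepted for a null distribution.
MIN_PERMUTATIONS = 100
DEFAULT_N_PERM = 1000


class TIError(ValueError):
    """Raised on degenerate coherence/TI inputs."""


@dataclass(frozen=True)
class BandSpec:
    """An inclusive integer-hertz bin range."""

    name: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.hi):
            raise TIError(f"invalid band bins [{self.lo}, {self.hi}]")

    def bins(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)


#: "All frequency bands" in this analysis: 1-20 Hz inclusive.
ALL_BAND = BandSpec("all", 1, 20)
#: Alpha rhythm band, 8-12 Hz inclusive.
ALPHA_BAND = BandSpec("alpha", 8, 12)
DEFAULT_BANDS: tuple[BandSpec, ...] = (ALL_BAND, ALPHA_BAND)


@dataclass(frozen=True)
class CoherenceSpectrum:
    """Magnitude-squared coherence at integer-Hz bins, averaged over K epochs."""

    freqs: np.ndarray  # Hz, one per bin (0, 1, 2, ...)
    values: np.ndarray  # C(f) in [0, 1]
    K: int

    def band_values(self, band: BandSpec) -> np.ndarray:
        if band.hi > self.freqs[-1]:
            raise TIError(
                f"band {band.name} ({band.lo}-{band.hi} Hz) exceeds spectrum "
                f"top bin {self.freqs[-1]:.0f} Hz"
            )
        mask = (self.freqs >= band.lo) & (self.freqs <= band.hi)
        return self.values[mask]


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null of band TI."""

    values: np.ndarray
    mean: float
    sd: float
    n_perm: int


@dataclass(frozen=True)
class TIResult:
    """Raw and permutation-normalized TI for one pair/band/region/communication."""

    raw_ti: float
    null_mean: float
    null_sd: float
    z: float
    n_perm: int
    ks_flag: bool
    K: int = 0


def epoch_spectra(epochs: np.ndarray, fs: float) -> np.ndarray:
    """Per-epoch DFT after linear detrend and Hann windowing.

    Parameters
    ----------
    epochs : ndarray, shape (K, n_samples)
        1-second epochs; ``n_samples`` must equal ``fs`` so bins are 1 Hz apart.

    Returns
    -------
    ndarray, complex, shape (K, n_samples // 2 + 1)
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2:
        raise TIError("epochs must be a (K x n_samples) matrix")
    n = epochs.shape[1]
    if n != int(round(fs)):
        raise TIError(f"each epoch must hold exactly fs={fs:g} samples (got {n})")
    detrended = signal.detrend(epochs, axis=1, type="linear")
    win = signal.windows.hann(n, sym=False)
    return np.fft.rfft(detrended * win[None, :], axis=1)


def _coherence_from_spectra(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    sxy = (X * np.conj(Y)).mean(axis=0)
    sxx = (np.abs(X) ** 2).mean(axis=0)
    syy = (np.abs(Y) ** 2).mean(axis=0)
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(sxy) ** 2 / denom
    c = np.where(denom > 0, c, 0.0)
    return np.clip(c, 0.0, 1.0)


def coherence_epochs(
    x_epochs: np.ndarray, y_epochs: np.ndarray, fs: float
) -> CoherenceSpectrum:
    """Epoch-averaged magnitude-squared coherence between two channels.

    C(f) = |<X Y*>|^2 / (<|X|^2><|Y|^2>) with <.> the mean over epochs. With a
    single epoch C would be identically 1, hence K >= 2 is required; note the
    estimate carries an upward bias of roughly 1/K under independence.
    """
    X = epoch_spectra(x_epochs, fs)
    Y = epoch_spectra(y_epochs, fs)
    if X.shape != Y.shape:
        raise TIError("x and y epoch sets differ in shape")
    K = X.shape[0]
    if K < 2:
        raise TIError("coherence degenerate at K=1")
    values = _coherence_from_spectra(X, Y)
    freqs = np.fft.rfftfreq(x_epochs.shape[1], d=1.0 / fs)
    return CoherenceSpectrum(freqs=freqs, values=values, K=K)


def band_ti(
    spectrum: CoherenceSpectrum, band: BandSpec, clip: float = COHERENCE_CLIP
) -> float:
    """Band TI: ``-sum ln(1 - C(f))`` over the band's integer-Hz bins."""
    c = np.minimum(spectrum.band_values(band), clip)
    return float(-np.log1p(-c).sum())


def _band_masks(freqs: np.ndarray, bands: tuple[BandSpec, ...]) -> list[np.ndarray]:
    return [(freqs >= b.lo) & (freqs <= b.hi) for b in bands]


def permutation_null(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    fs: float,
    band: BandSpec,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> NullDistribution:
    """Null distribution of band TI under random epoch re-pairing.

    Each permutation shuffles the order of the y epochs against the x epochs
    (uniform permutation, fixed points allowed), destroying the cross-subject
    alignment while preserving each subject's own spectra, and band TI is
    recomputed. Autospectra are permutation-invariant, so only the
    cross-spectrum is recomputed per draw.
    """
    nulls = _permutation_nulls_multi(x_epochs, y_epochs, fs, (band,), n_perm, seed)
    return nulls[0]


def _permutation_nulls_multi(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...],
    n_perm: int,
    seed: int | np.random.Generator | None,
) -> list[NullDistribution]:
    X = epoch_spectra(x_epochs, fs)
    Y = epoch_spectra(y_epochs, fs)
    freqs = np.fft.rfftfreq(x_epochs.shape[1], d=1.0 / fs)
    return nulls_from_spectra(X, Y, freqs, bands, n_perm, seed)


def nulls_from_spectra(
    X: np.ndarray,
    Y: np.ndarray,
    freqs: np.ndarray,
    bands: tuple[BandSpec, ...],
    n_perm: int,
    seed: int | np.random.Generator | None,
    chunk: int = 250,
) -> list[NullDistribution]:
    """Permutation nulls computed from precomputed per-epoch spectra.

    Lets callers that analyze many pairs over the same epochs reuse each
    subject's FFTs; :func:`permutation_null` is the array-level front end.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise TIError(f"n_perm={n_perm} below the floor of {MIN_PERMUTATIONS}")
    if X.shape != Y.shape:
        raise TIError("x and y epoch sets differ in shape")
    K, F = X.shape
    if K < 2:
        raise TIError("coherence degenerate at K=1")
    masks = _band_masks(freqs, bands)
    for b in bands:
        if b.hi > freqs[-1]:
            raise TIError(f"band {b.name} exceeds the spectrum")

    sxx = (np.abs(X) ** 2).mean(axis=0)
    syy = (np.abs(Y) ** 2).mean(axis=0)
    denom = sxx * syy
    safe = denom > 0

    rng = np.random.default_rng(seed)
    out = np.empty((len(bands), n_perm))
    Xc = np.conj(X)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, K)), axis=1)
        # (m, K, F): cross-spectra of x against permuted y, then epoch-mean
        sxy = np.einsum("kf,mkf->mf", Xc, Y[perms]) / K
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(sxy) ** 2 / denom[None, :]
        c = np.where(safe[None, :], c, 0.0)
        c = np.minimum(np.clip(c, 0.0, 1.0), COHERENCE_CLIP)
        logc = -np.log1p(-c)
        for i, mask in enumerate(masks):
            out[i, done : done + m] = logc[:, mask].sum(axis=1)
        done += m

    nulls = []
    for i in range(len(bands)):
        vals = out[i]
        sd = float(vals.std(ddof=1))
        if sd == 0:
            raise TIError("degenerate null: permutation TI has zero variance")
        nulls.append(
            NullDistribution(values=vals, mean=float(vals.mean()), sd=sd, n_perm=n_perm)
        )
    return nulls


def normalize_ti(raw_ti: float, null: NullDistribution, K: int = 0) -> TIResult:
    """z-score the observed TI against its permutation null.

    ``ks_flag`` is raised when a Lilliefors-corrected Kolmogorov-Smirnov test
    rejects normality of the null sample at alpha = .05 (the reference normal
    has the sample's own mean and SD, hence the fitted-parameter correction).
    """
    if null.sd <= 0:
        raise TIError("degenerate null: zero SD")
    z = (raw_ti - null.mean) / null.sd
    _, p = lilliefors(null.values, dist="norm", pvalmethod="table")
    return TIResult(
        raw_ti=float(raw_ti),
        null_mean=null.mean,
        null_sd=null.sd,
        z=float(z),
        n_perm=null.n_perm,
        ks_flag=bool(p < 0.05),
        K=K,
    )


def normalized_ti(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> dict[str, TIResult]:
    """Observed and permutation-normalized TI for several bands at once.

    The permutation draws are shared across bands (the cross-spectrum is
    computed once per permutation and integrated over each band), which keeps
    the cost of multi-band analysis close to single-band.
    """
    X = epoch_spectra(x_epochs, fs)
    Y = epoch_spectra(y_epochs, fs)
    freqs = np.fft.rfftfreq(x_epochs.shape[1], d=1.0 / fs)
    return normalized_ti_from_spectra(X, Y, freqs, bands, n_perm, seed)


def normalized_ti_from_spectra(
    X: np.ndarray,
    Y: np.ndarray,
    freqs: np.ndarray,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = None,
) -> dict[str, TIResult]:
    """Spectra-level counterpart of :func:`normalized_ti`."""
    if X.shape != Y.shape:
        raise TIError("x and y epoch sets differ in shape")
    K = X.shape[0]
    if K < 2:
        raise TIError("coherence degenerate at K=1")
    spectrum = CoherenceSpectrum(
        freqs=freqs, values=_coherence_from_spectra(X, Y), K=K
    )
    nulls = nulls_from_spectra(X, Y, freqs, bands, n_perm, seed)
    results: dict[str, TIResult] = {}
    for band, null in zip(bands, nulls):
        raw = band_ti(spectrum, band)
        results[band.name] = normalize_ti(raw, null, K=spectrum.K)
    return results
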