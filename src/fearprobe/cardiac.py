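"""Heart-rate extraction from EEG via extended-infomax ICA.

The cardiac field of the heart projects into every EEG electrode. The
chain implemented here mirrors the classical artifact-separation route:
concatenate one condition's trials into a continuous stretch, decompose
with the extended information-maximization ICA (natural-gradient update
with sub-/super-Gaussian switching), identify the activation rows whose
time courses look cardiac (periodic within a plausible beats-per-minute
band and spiky, i.e. high excess kurtosis), detect beats on the best
row, and convert beat times to a rate. Corrected EEG can be rebuilt as
``y' = X^-1 v'`` with the cardiac rows of the activation matrix zeroed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from fearprobe.core import (
    EpochSet,
    HeartRateEstimate,
    ICADecomposition,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceError",
    "NoCardiacComponentError",
    "concatenate_condition",
    "ExtendedInfomaxICA",
    "extended_infomax",
    "identify_cardiac",
    "detect_beats",
    "estimate_heart_rate",
    "reconstruct_without",
]


class ConvergenceError(RuntimeError):
    """ICA failed to converge; carries the last weight delta."""

    def __init__(self, n_iter: int, delta: float):
        super().__init__(
            f"extended infomax did not converge in {n_iter} iterations "
            f"(last weight delta {delta:.3e})"
        )
        self.n_iter = n_iter
        self.delta = delta


class NoCardiacComponentError(RuntimeError):
    """No ICA component met the cardiac criteria."""


def _concat_taper_envelope(
    n_segments: int, n_seg: int, fs_hz: float, taper_s: float = 0.05
) -> np.ndarray:
    """Gain envelope applied by :func:`concatenate_condition`."""
    taper = np.ones(n_seg)
    n_ramp = int(round(taper_s * fs_hz))
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        taper[:n_ramp] = ramp
        taper[-n_ramp:] = ramp[::-1]
    return np.tile(taper, n_segments)


def concatenate_condition(
    epochs: EpochSet,
    condition: str,
    n_trials: int | None = None,
    segment_s: float = 5.0,
    taper_s: float = 0.05,
) -> np.ndarray:
    """Concatenate one condition's cue windows into a continuous matrix.

    Takes the ``[0, segment_s)`` window of the first ``n_trials`` epochs
    of ``condition`` (all of them by default) and joins them in trial
    order, so e.g. 36 five-second trials give 180 s and 24 give 120 s.
    A raised-cosine taper of ``taper_s`` at each segment boundary avoids
    spurious spikes at the joins.
    """
    mask = epochs.conditions == condition
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise InvalidParameterError(f"no epochs with condition {condition!r}")
    if n_trials is not None:
        if n_trials > idx.size:
            raise InvalidParameterError(
                f"requested {n_trials} trials but only {idx.size} available"
            )
        idx = idx[:n_trials]
    fs = epochs.fs_hz
    n_seg = int(round(segment_s * fs))
    t_mask = (epochs.times_ms >= 0) & (epochs.times_ms < segment_s * 1000.0)
    if t_mask.sum() < n_seg:
        raise InvalidParameterError(
            f"epochs cover {t_mask.sum() / fs:.2f} s of cue window; "
            f"{segment_s} s segments requested"
        )
    sel = np.flatnonzero(t_mask)[:n_seg]
    taper = np.ones(n_seg)
    n_ramp = int(round(taper_s * fs))
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        taper[:n_ramp] = ramp
        taper[-n_ramp:] = ramp[::-1]
    segments = [epochs.data[i][:, sel] * taper for i in idx]
    return np.hstack(segments)


class ExtendedInfomaxICA:
    """Extended information-maximization ICA (natural gradient).

    A blind source separation estimator in the scikit-learn style:
    ``fit`` expects data of shape (n_samples, n_features) and exposes
    ``components_`` (the unmixing matrix applied to centred data) and
    ``mixing_`` (its pseudoinverse). The extended variant estimates a
    sub-/super-Gaussian switching sign per component each pass, so both
    spiky (cardiac) and flat-topped (line/sinusoidal) sources separate.

    Parameters
    ----------
    n_components : int or None
        PCA pre-whitening dimension; None keeps all channels.
    learning_rate : float or None
        Initial natural-gradient step size (None: 0.01 / log(n^2), the
        conventional dimension-scaled default); multiplied by
        ``anneal_factor`` whenever successive weight updates oscillate
        (angle > 60 degrees).
    tol : float
        Convergence threshold on the per-pass weight change norm.
    """

    def __init__(
        self,
        n_components: int | None = None,
        learning_rate: float | None = None,
        max_iter: int = 500,
        tol: float = 1e-7,
        anneal_factor: float = 0.9,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol
        self.anneal_factor = anneal_factor
        self.random_state = random_state

    # minimal sklearn estimator API
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "learning_rate": self.learning_rate,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "anneal_factor": self.anneal_factor,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "ExtendedInfomaxICA":
        for key, value in params.items():
            if key not in self.get_params():
                raise InvalidParameterError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: np.ndarray) -> "ExtendedInfomaxICA":
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise InvalidParameterError("X must be 2-D (n_samples, n_features)")
        n_samples, n_features = X.shape
        if n_samples < 4 * n_features:
            raise InvalidParameterError("need many more samples than features")
        n_comp = self.n_components or n_features
        if n_comp > n_features:
            raise InvalidParameterError("n_components cannot exceed n_features")
        rng = np.random.default_rng(self.random_state)

        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_

        # PCA whitening, capped at the numerical rank (interpolated
        # channels make the covariance singular)
        cov = Xc.T @ Xc / n_samples
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        rank = int(np.sum(evals > max(evals[0], 0.0) * 1e-10))
        if rank < 1:
            raise InvalidParameterError("data has zero variance")
        if n_comp > rank:
            logger.info("reducing n_components %d -> numerical rank %d", n_comp, rank)
            n_comp = rank
        evals, evecs = evals[:n_comp], evecs[:, :n_comp]
        whiten = evecs / np.sqrt(evals)  # (features, comp)
        Z = Xc @ whiten  # (samples, comp), identity covariance

        W = np.eye(n_comp)
        # conventional dimension-scaled initial rate
        lr = self.learning_rate
        if lr is None:
            lr = 0.01 / max(np.log(float(n_comp) ** 2), 1.0)
        block = max(int(np.floor(np.sqrt(n_samples / 3.0))), 8)
        eye = np.eye(n_comp)
        prev_delta_vec = None
        delta = np.inf
        self.converged_ = False
        iteration = 0

        def switching_signs(W):
            sample = Z[:: max(1, n_samples // 6000)] @ W.T
            m2 = np.mean(sample**2, axis=0)
            m4 = np.mean(sample**4, axis=0)
            kurt = m4 / np.maximum(m2**2, 1e-12) - 3.0
            return np.where(kurt >= 0, 1.0, -1.0)

        # phase 1: stochastic block passes (fast initial separation);
        # phase 2: full-batch natural gradient (deterministic polish, so
        # the tolerance is met at a true stationary point)
        n_stochastic = min(max(self.max_iter // 3, 50), self.max_iter)
        lr0 = lr
        delta_prev = np.inf
        while iteration < self.max_iter:
            iteration += 1
            stochastic = iteration <= n_stochastic
            if iteration == n_stochastic + 1:
                lr = max(lr, lr0 / 2)  # polish phase restarts the step size
                delta_prev = np.inf
            W_old = W.copy()
            K = np.diag(switching_signs(W))

            blew_up = False
            if stochastic:
                order_idx = rng.permutation(n_samples)
                for start_i in range(0, n_samples - block + 1, block):
                    u = Z[order_idx[start_i : start_i + block]] @ W.T
                    tanh_u = np.tanh(u)
                    grad = eye - (K @ (tanh_u.T @ u) + u.T @ u) / block
                    W = W + lr * grad @ W
                    if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e6:
                        blew_up = True
                        break
            else:
                u = Z @ W.T
                tanh_u = np.tanh(u)
                grad = eye - (K @ (tanh_u.T @ u) + u.T @ u) / n_samples
                W = W + lr * grad @ W
                if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e6:
                    blew_up = True
            if blew_up:
                W = np.eye(n_comp)
                lr *= 0.5
                prev_delta_vec = None
                logger.warning("weight blow-up; restarting with learning rate %g", lr)
                continue

            delta_vec = (W - W_old).ravel()
            delta = float(np.linalg.norm(delta_vec))
            if delta > 10.0 * np.linalg.norm(W_old):  # divergence: restart slower
                W = np.eye(n_comp)
                lr *= 0.5
                prev_delta_vec = None
                logger.warning("weight divergence; restarting with learning rate %g", lr)
                continue
            if stochastic:
                if prev_delta_vec is not None:
                    denom = np.linalg.norm(delta_vec) * np.linalg.norm(prev_delta_vec)
                    if denom > 0:
                        cos_angle = float(delta_vec @ prev_delta_vec / denom)
                        if cos_angle < 0.5:  # oscillation: angle > 60 degrees
                            lr *= self.anneal_factor
            else:
                # deterministic phase: grow the step while the update
                # shrinks, back off when it oscillates
                if delta < delta_prev:
                    lr = min(lr * 1.05, 2 * lr0)
                else:
                    lr *= 0.7
                delta_prev = delta
            prev_delta_vec = delta_vec
            if not stochastic and delta < self.tol:
                self.converged_ = True
                break

        self.n_iter_ = iteration
        self.final_delta_ = delta
        if not self.converged_:
            raise ConvergenceError(self.n_iter_, delta)
        self.components_ = W @ whiten.T  # (comp, features), applied to centred data
        self.mixing_ = np.linalg.pinv(self.components_)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, S: np.ndarray) -> np.ndarray:
        return np.asarray(S, float) @ self.mixing_.T + self.mean_


def extended_infomax(
    y: np.ndarray,
    n_components: int | None = None,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> ICADecomposition:
    """Decompose channels x time data: activations ``v = X (y - mean)``.

    ``n_components`` defaults to ``min(n_channels, 20)`` (PCA
    pre-whitening); the unmixing applies to mean-removed data and the
    mixing matrix is its pseudoinverse, whose columns give each
    component's projection strengths onto the sensors.
    """
    y = np.asarray(y, float)
    if y.ndim != 2:
        raise InvalidParameterError("y must be channels x time")
    n_ch = y.shape[0]
    if n_components is None:
        n_components = min(n_ch, 20)
    est = ExtendedInfomaxICA(
        n_components=n_components, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(y.T)
    return ICADecomposition(
        unmixing=est.components_,
        mixing=est.mixing_,
        mean=est.mean_,
        activations=est.transform(y.T).T,
        n_iter=est.n_iter_,
        converged=est.converged_,
        final_delta=est.final_delta_,
    )


def _band_autocorr_peak(
    x: np.ndarray, fs_hz: float, bpm_range: tuple[float, float],
    smooth_s: float = 0.12,
) -> float:
    """Max normalized autocorrelation at lags inside the beat-period band.

    Computed on the smoothed energy envelope: raw spike trains with
    physiological beat-to-beat jitter decorrelate at one-period lag, the
    envelope does not.
    """
    x = np.abs(np.asarray(x, float))
    n_smooth = max(1, int(round(smooth_s * fs_hz)))
    kernel = np.ones(n_smooth) / n_smooth
    x = np.convolve(x, kernel, mode="same")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    n = len(x)
    # FFT autocorrelation, biased normalization
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / denom
    lag_lo = int(np.floor(60.0 / bpm_range[1] * fs_hz))
    lag_hi = int(np.ceil(60.0 / bpm_range[0] * fs_hz))
    lag_hi = min(lag_hi, n - 1)
    if lag_lo >= lag_hi:
        return 0.0
    return float(acf[lag_lo : lag_hi + 1].max())


def _excess_kurtosis(x: np.ndarray) -> float:
    x = x - x.mean()
    m2 = np.mean(x**2)
    if m2 == 0:
        return 0.0
    return float(np.mean(x**4) / m2**2 - 3.0)


def identify_cardiac(
    decomp: ICADecomposition,
    fs_hz: float,
    bpm_range: tuple[float, float] = (40.0, 140.0),
    acf_thresh: float = 0.3,
    kurt_thresh: float = 3.0,
    n_max: int = 2,
) -> list[int]:
    """Flag activation rows that look cardiac.

    A row qualifies when it is (a) periodic -- its autocorrelation has a
    peak above ``acf_thresh`` at a lag inside the band implied by
    ``bpm_range`` -- and (b) spiky, with excess kurtosis above
    ``kurt_thresh`` (the QRS complex dominates the time course). At most
    ``n_max`` rows are returned, best combined score first; an empty
    result is a warning, not an error (heart rate is then unavailable).
    """
    scores = []
    for i, row in enumerate(decomp.activations):
        acf = _band_autocorr_peak(row, fs_hz, bpm_range)
        kurt = _excess_kurtosis(row)
        if acf > acf_thresh and kurt > kurt_thresh:
            scores.append((acf + kurt / 100.0, i))
    if not scores:
        warnings.warn("no ICA component met the cardiac criteria", stacklevel=2)
        return []
    scores.sort(reverse=True)
    rows = [i for _, i in scores[:n_max]]
    decomp.cardiac_rows = rows
    return rows


def detect_beats(
    activation: np.ndarray,
    fs_hz: float,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """Beat times from a cardiac activation row.

    QRS-style energy detection, polarity invariant: the trace is
    median-centred, band-passed to the QRS band (5-30 Hz), squared and
    smoothed (120 ms); energy peaks at least ``refractory_s`` apart
    above an adaptive threshold (relative to the typical strong peak)
    are kept, a search-back pass recovers attenuated beats inside gaps
    longer than 1.6 typical intervals, and each beat time is refined to
    the sharpest deflection nearby.
    """
    from scipy.signal import filtfilt, find_peaks, firwin

    x = np.asarray(activation, float)
    if x.size < fs_hz:
        return np.array([])
    x = x - np.median(x)
    if not np.any(x):
        return np.array([])
    band = firwin(65, [5.0, min(30.0, 0.45 * fs_hz)], pass_zero=False, fs=fs_hz)
    z = filtfilt(band, [1.0], x)
    n_smooth = max(1, int(round(0.12 * fs_hz)))
    energy = filtfilt(np.ones(n_smooth) / n_smooth, [1.0], z**2)
    dist = max(1, int(round(refractory_s * fs_hz)))
    cand, _ = find_peaks(energy, distance=dist)
    if cand.size == 0:
        return np.array([])
    heights = energy[cand]
    floor = 0.1 * np.percentile(heights, 95)
    strong = heights[heights > floor]
    if strong.size == 0:
        return np.array([])
    thr = 0.35 * np.median(strong)
    beats, _ = find_peaks(energy, distance=dist, height=thr)
    if beats.size >= 3:
        # search-back: recover attenuated beats in over-long gaps
        med = np.median(np.diff(beats))
        extra = []
        low_thr = 0.12 * np.median(strong)
        for a, b in zip(beats[:-1], beats[1:]):
            if b - a > 1.6 * med:
                seg, props = find_peaks(energy[a + dist : b - dist + 1],
                                        distance=dist, height=low_thr)
                # at most as many beats as the gap can physiologically hold
                k_max = max(int(round((b - a) / med)) - 1, 0)
                if seg.size > k_max:
                    keep = np.argsort(props["peak_heights"])[::-1][:k_max]
                    seg = seg[np.sort(keep)]
                extra.extend(seg + a + dist)
        if extra:
            beats = np.unique(np.concatenate([beats, extra]))
    # refine each beat to the sharpest nearby deflection
    w = max(1, int(round(0.08 * fs_hz)))
    refined = []
    for i in beats:
        a, b = max(0, i - w), min(len(z), i + w + 1)
        refined.append(a + int(np.argmax(np.abs(z[a:b]))))
    return np.unique(refined) / fs_hz


def estimate_heart_rate(
    epochs: EpochSet,
    condition: str,
    n_trials: int | None = None,
    segment_s: float = 5.0,
    n_components: int | None = None,
    seed: int | None = 0,
    bpm_range: tuple[float, float] = (40.0, 140.0),
    subtract_evoked: bool = True,
) -> HeartRateEstimate:
    """Concatenate, decompose, identify the cardiac row, count beats.

    The rate is ``60 * (n_beats - 1) / (t_last - t_first)`` over the
    concatenated stretch of one condition's trials. By default the
    condition's time-locked average is subtracted from every epoch
    first: the evoked response recurs at the same latency in each
    concatenated segment and would otherwise leak into the cardiac
    component as a spurious periodic spike.
    """
    if subtract_evoked:
        mask = epochs.conditions == condition
        if mask.any():
            data = epochs.data.copy()
            data[mask] -= data[mask].mean(axis=0)
            epochs = EpochSet(
                data=data, times_ms=epochs.times_ms, conditions=epochs.conditions,
                us_paired=epochs.us_paired, fs_hz=epochs.fs_hz,
                layout=epochs.layout, provenance=epochs.provenance,
            )
    y = concatenate_condition(epochs, condition, n_trials=n_trials, segment_s=segment_s)
    decomp = extended_infomax(y, n_components=n_components, seed=seed)
    rows = identify_cardiac(decomp, epochs.fs_hz, bpm_range=bpm_range)
    if not rows:
        raise NoCardiacComponentError(
            f"no cardiac component found in condition {condition!r}"
        )
    # undo the join taper (its shape is known) so beats near segment
    # boundaries are not attenuated below the detection threshold
    act = decomp.activations[rows[0]]
    n_seg = int(round(segment_s * epochs.fs_hz))
    env = _concat_taper_envelope(act.size // n_seg, n_seg, epochs.fs_hz)
    act = act / np.maximum(env, 0.25)
    beats = detect_beats(act, epochs.fs_hz)
    if beats.size < 2:
        raise NoCardiacComponentError("fewer than 2 beats detected")
    span = beats[-1] - beats[0]
    return HeartRateEstimate(
        condition=condition,
        bpm=float(60.0 * (beats.size - 1) / span),
        n_beats=int(beats.size),
        duration_s=y.shape[1] / epochs.fs_hz,
        beat_times_s=beats,
    )


def reconstruct_without(decomp: ICADecomposition, rows: list[int]) -> np.ndarray:
    """Artifact-reduced channels x time data: ``y' = X^-1 v'``.

    ``v'`` is the activation matrix with the given rows zeroed; removing
    no rows returns the input data (to numerical tolerance, at full
    component rank) and removing all rows leaves only the channel means.
    """
    v = decomp.activations.copy()
    if rows:
        v[np.asarray(rows, int)] = 0.0
    return decomp.mixing @ v + decomp.mean[:, None]
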