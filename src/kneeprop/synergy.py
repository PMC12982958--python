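"""EMG muscle-synergy extraction.

Event-locked EMG segments (fish catches: the 2 s leading up to the catch;
carrot groups: first through ninth collection of a complete group) are
band-limited with fifth-order Butterworth filters (low-pass 30 Hz, then
high-pass 4 Hz), detrended, rectified, and normalized per channel by its
maximum and then its SD (unit variance).  Non-negative matrix factorization
``E ≈ W·H`` extracts muscle weights; the synergy count is the smallest k
whose variance-accounted-for (uncentered, 1 − ‖E − WH‖²/‖E‖²) meets a
threshold of 90/85/80%.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .protocol import GameEvent
from .streams import EMGStream, MUSCLES

log = logging.getLogger(__name__)

N_MUSCLES = len(MUSCLES)


@dataclass
class EMGSegment:
    matrix: np.ndarray             # (7, n_samples)
    fs: float
    game: str = ""
    event_id: str = ""
    window: tuple[float, float] = (0.0, 0.0)
    movement_class: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != N_MUSCLES:
            raise ValueError(f"EMG segment must be (7, n), got {self.matrix.shape}")


@dataclass
class SynergyModel:
    W: np.ndarray                  # (7, k), non-negative, unit-norm columns
    H: np.ndarray                  # (k, n), non-negative
    vaf: float
    k: int


def segment_emg(
    stream: EMGStream,
    events: list[GameEvent],
    fish_window: float = 2.0,
) -> list[EMGSegment]:
    """Cut task-locked segments out of an EMG stream.

    Fish catches yield ``[t − 2 s, t]``; a complete carrot group (all nine
    ordinals collected) yields ``[t_first, t_ninth]``.  Misses and
    incomplete groups yield nothing; windows falling outside the recording
    are skipped with a log message.
    """
    t0, t1 = stream.span
    segments: list[EMGSegment] = []

    def emit(start, end, game, event_id, cls):
        if start < t0 - 1e-9 or end > t1 + 1e-9:
            log.warning("skipping EMG segment %s: window [%.2f, %.2f] outside stream", event_id, start, end)
            return
        mat = stream.window(start, end)
        segments.append(EMGSegment(matrix=mat, fs=stream.fs, game=game,
                                   event_id=event_id, window=(start, end),
                                   movement_class=cls))

    for i, ev in enumerate(e for e in events if e.kind == "fish_caught"):
        emit(ev.t - fish_window, ev.t, "fish", f"fish_{i}", f"trail_{ev.trail}")

    by_group: dict[int, dict[int, float]] = {}
    for ev in events:
        if ev.kind == "carrot_collected":
            by_group.setdefault(ev.group, {})[ev.ordinal] = ev.t
    for g, ordinals in sorted(by_group.items()):
        if set(ordinals) == set(range(1, 10)):
            emit(ordinals[1], ordinals[9], "bunny", f"group_{g}", "squat_group")
        else:
            log.info("skipping incomplete carrot group %s (%d of 9)", g, len(ordinals))
    return segments


class EMGPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless EMG conditioning chain.

    Order of operations per channel: Butterworth low-pass (30 Hz, order 5)
    → Butterworth high-pass (4 Hz, order 5) → subtract mean → rectify
    (absolute value) → divide by the channel maximum → divide by the SD of
    the result, leaving every channel non-negative with unit variance.

    Filtering is zero-phase (forward-backward) by default, appropriate for
    offline analysis; ``causal=True`` switches to a single forward pass.
    """

    def __init__(self, lowpass_hz: float = 30.0, highpass_hz: float = 4.0,
                 order: int = 5, causal: bool = False):
        self.lowpass_hz = lowpass_hz
        self.highpass_hz = highpass_hz
        self.order = order
        self.causal = causal

    def fit(self, X=None, y=None):
        return self

    def _filter(self, x: np.ndarray, fs: float) -> np.ndarray:
        nyq = fs / 2.0
        if not self.highpass_hz < self.lowpass_hz < nyq:
            raise ValueError(
                f"filter cutoffs ({self.highpass_hz}, {self.lowpass_hz}) Hz invalid for fs={fs}"
            )
        sos_lp = signal.butter(self.order, self.lowpass_hz / nyq, "lowpass", output="sos")
        sos_hp = signal.butter(self.order, self.highpass_hz / nyq, "highpass", output="sos")
        if self.causal:
            x = signal.sosfilt(sos_lp, x, axis=-1)
            return signal.sosfilt(sos_hp, x, axis=-1)
        x = signal.sosfiltfilt(sos_lp, x, axis=-1)
        return signal.sosfiltfilt(sos_hp, x, axis=-1)

    def transform(self, segment: EMGSegment) -> EMGSegment:
        mat = segment.matrix
        if mat.shape[1] <= 3 * (self.order + 1):
            raise ValueError("EMG segment too short for the filter order")
        filtered = self._filter(mat, segment.fs)
        detrended = filtered - filtered.mean(axis=1, keepdims=True)
        rectified = np.abs(detrended)
        peak = rectified.max(axis=1, keepdims=True)
        dead = np.nonzero(peak.ravel() == 0)[0]
        if dead.size:
            raise ValueError(f"all-zero EMG channel(s): {[MUSCLES[i] for i in dead]}")
        scaled = rectified / peak
        sd = scaled.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            dead = [MUSCLES[i] for i in np.nonzero(sd.ravel() == 0)[0]]
            raise ValueError(f"constant EMG channel(s) after rectification: {dead}")
        out = scaled / sd
        return EMGSegment(matrix=out, fs=segment.fs, game=segment.game,
                          event_id=segment.event_id, window=segment.window,
                          movement_class=segment.movement_class)


def preprocess(segment: EMGSegment, **kwargs) -> EMGSegment:
    """Functional form of :class:`EMGPreprocessor`."""
    return EMGPreprocessor(**kwargs).transform(segment)


def vaf(E: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Variance accounted for by a reconstruction: uncentered
    ``1 − ‖E − W·H‖²_F / ‖E‖²_F``, clipped to [0, 1]."""
    E = np.asarray(E, dtype=float)
    total = float(np.sum(E**2))
    if total == 0:
        raise ValueError("VAF undefined for an all-zero matrix")
    resid = float(np.sum((E - W @ H) ** 2))
    return float(np.clip(1.0 - resid / total, 0.0, 1.0))


def _normalize_columns(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return W / norms, H * norms[:, None]


class SynergyNMF(BaseEstimator):
    """Best-of-restarts non-negative matrix factorization of one segment.

    Multiplicative updates, ``restarts`` random initializations (plus any
    warm start supplied), keeping the fit with the lowest reconstruction
    error.  After fitting, ``W_`` has unit-Euclidean-norm columns with the
    scale pushed into ``H_``.

    Attributes: ``W_ (7, k)``, ``H_ (k, n)``, ``vaf_``.
    """

    def __init__(self, k: int = 3, restarts: int = 10, max_iter: int = 1000,
                 tol: float = 1e-6, seed: int = 0):
        self.k = k
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X, y=None, warm_start: tuple[np.ndarray, np.ndarray] | None = None):
        E = X.matrix if isinstance(X, EMGSegment) else np.asarray(X, dtype=float)
        if not 1 <= self.k <= E.shape[0]:
            raise ValueError(f"synergy count k={self.k} outside [1, {E.shape[0]}]")
        if np.any(E < 0):
            raise ValueError("NMF requires a non-negative matrix")
        rng = np.random.default_rng(self.seed)
        best = None
        inits: list[tuple | None] = [None] * self.restarts
        if warm_start is not None:
            inits.append(warm_start)
        for init in inits:
            kwargs = dict(n_components=self.k, solver="mu", max_iter=self.max_iter,
                          tol=self.tol, beta_loss="frobenius")
            # best-of-restarts tolerates candidates stopped at max_iter
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                if init is None:
                    model = NMF(**kwargs, init="random",
                                random_state=int(rng.integers(0, 2**31 - 1)))
                    W = model.fit_transform(E)
                else:
                    W0, H0 = init
                    model = NMF(**kwargs, init="custom")
                    W = model.fit_transform(E, W=np.ascontiguousarray(W0, dtype=float),
                                            H=np.ascontiguousarray(H0, dtype=float))
            H = model.components_
            err = float(np.linalg.norm(E - W @ H))
            if best is None or err < best[0]:
                best = (err, W, H)
        _, W, H = best
        self.W_, self.H_ = _normalize_columns(W, H)
        self.vaf_ = vaf(E, self.W_, self.H_)
        return self

    def to_model(self) -> SynergyModel:
        return SynergyModel(W=self.W_, H=self.H_, vaf=self.vaf_, k=self.k)


def fit_nmf(E, k: int, restarts: int = 10, seed: int = 0, **kwargs) -> SynergyModel:
    """Fit a k-synergy NMF and return the (column-normalized) model."""
    est = SynergyNMF(k=k, restarts=restarts, seed=seed, **kwargs)
    return est.fit(E).to_model()


def vaf_curve(E, k_max: int = N_MUSCLES, restarts: int = 10, seed: int = 0,
              max_iter: int = 1000, tol: float = 1e-6) -> tuple[np.ndarray, list[SynergyModel]]:
    """VAF at k = 1..k_max with nested warm starts.

    The best k-synergy solution (padded with a small random extra column)
    seeds one of the candidates at k+1, which makes the returned VAF curve
    non-decreasing in k up to solver tolerance.
    """
    E_mat = E.matrix if isinstance(E, EMGSegment) else np.asarray(E, dtype=float)
    rng = np.random.default_rng(seed)
    vafs, models = [], []
    warm = None
    for k in range(1, k_max + 1):
        est = SynergyNMF(k=k, restarts=restarts, max_iter=max_iter, tol=tol,
                         seed=int(rng.integers(0, 2**31 - 1)))
        est.fit(E_mat, warm_start=warm)
        vafs.append(est.vaf_)
        models.append(est.to_model())
        scale = max(E_mat.mean(), 1e-12)
        pad_w = rng.uniform(1e-6, 1e-3, (E_mat.shape[0], 1)) * scale
        pad_h = rng.uniform(1e-6, 1e-3, (1, E_mat.shape[1])) * scale
        warm = (np.hstack([est.W_, pad_w]), np.vstack([est.H_, pad_h]))
    return np.asarray(vafs), models


def k_from_vaf_curve(vafs: np.ndarray, threshold: float) -> int:
    """Smallest k whose VAF reaches ``threshold`` percent (the largest
    fitted k if none does)."""
    if not 0.0 < threshold < 100.0:
        raise ValueError("threshold must lie in (0, 100) percent")
    qualifying = np.nonzero(np.asarray(vafs) >= threshold / 100.0)[0]
    return int(qualifying[0]) + 1 if qualifying.size else len(vafs)


def select_synergy_number(E, threshold: float = 85.0, restarts: int = 10,
                          seed: int = 0, **kwargs) -> tuple[int, np.ndarray]:
    """Smallest k in 1..7 whose VAF reaches ``threshold`` percent (7 if none
    does).  Returns ``(k, vaf_curve)``.  To evaluate several thresholds,
    compute :func:`vaf_curve` once and apply :func:`k_from_vaf_curve`."""
    vafs, _ = vaf_curve(E, restarts=restarts, seed=seed, **kwargs)
    return k_from_vaf_curve(vafs, threshold), vafs


def match_synergies(W_a: np.ndarray, W_b: np.ndarray):
    """Optimal one-to-one pairing of two weight matrices' columns by total
    cosine similarity (exhaustive over permutations, fine for k ≤ 7).

    Returns ``(pairs, similarities)`` where ``pairs[i] = (col_a, col_b)``;
    with unequal synergy counts, min(k) columns are matched and the rest
    reported unmatched via the pairs of the larger matrix being absent.
    """
    W_a = np.asarray(W_a, dtype=float)
    W_b = np.asarray(W_b, dtype=float)
    if W_a.shape[0] != W_b.shape[0]:
        raise ValueError("weight matrices must share the muscle dimension")
    ka, kb = W_a.shape[1], W_b.shape[1]
    if ka != kb:
        log.warning("matching %d vs %d synergies: pairing min(k)", ka, kb)

    def unit(W):
        n = np.linalg.norm(W, axis=0)
        n[n == 0] = 1.0
        return W / n

    cos = unit(W_a).T @ unit(W_b)          # (ka, kb)
    k = min(ka, kb)
    best_perm, best_total = None, -np.inf
    small, large = (range(ka), range(kb)) if ka <= kb else (range(kb), range(ka))
    for subset in itertools.permutations(large, k):
        total = sum(
            cos[i, j] if ka <= kb else cos[j, i]
            for i, j in zip(small, subset)
        )
        if total > best_total:
            best_total, best_perm = total, subset
    pairs = [
        ((i, j) if ka <= kb else (j, i)) for i, j in zip(small, best_perm)
    ]
    sims = np.array([cos[i, j] for i, j in pairs])
    return pairs, np.clip(sims, 0.0, 1.0)
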