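"""Wave-dynamics metrics of simulated AF episodes.

* dominant frequency (DF): frequency of maximal Welch power in a
  physiological search band (default 2.5-20 Hz), per node and as a map
  mean — high-DF sites are putative AF drivers;
* Smax: maximal slope of the action-potential-duration restitution curve
  (APD90 vs preceding diastolic interval), fitted per node with a
  mono-exponential; slopes above ~1 favor wave-break;
* AFCL: mean interval between successive local activations;
* episode outcome: AF (fibrillatory), AT (organized tachycardia) or
  terminated; AF -> {AT, terminated} counts as defragmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .tissue import SimulationRecord

DF_BAND = (2.5, 20.0)     # Hz
DF_RESOLUTION = 0.05      # Hz, maximum spectral bin spacing
WELCH_SEG_S = 2.0         # Welch segment length, s
POWER_FLOOR = 1e-6        # in-band / broadband power ratio for "defined"


class NyquistError(ValueError):
    """Sampling rate too low for the requested search band."""


def _welch_df(x: np.ndarray, rate: float, band: tuple[float, float]):
    """Vectorized Welch DF over the last axis; returns (df, defined)."""
    lo, hi = band
    if rate <= 2 * hi:
        raise NyquistError(f"rate {rate} Hz must exceed twice the band top {hi} Hz")
    n = x.shape[-1]
    if n < 2 * rate:
        raise ValueError("need at least 2 s of signal for DF estimation")
    nperseg = min(n, int(round(WELCH_SEG_S * rate)))
    nfft = max(nperseg, int(np.ceil(rate / DF_RESOLUTION)))
    x2 = x.reshape(-1, n)
    df = np.empty(x2.shape[0])
    defined = np.empty(x2.shape[0], dtype=bool)
    chunk = 128  # keep the zero-padded spectra memory-bounded
    f = None
    for s in range(0, x2.shape[0], chunk):
        f, p = sps.welch(x2[s:s + chunk], fs=rate, window="hann",
                         nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft,
                         detrend="constant", axis=-1)
        sel = (f >= lo) & (f <= hi)
        pin = p[..., sel]
        total = p.sum(axis=-1)
        inband = pin.sum(axis=-1)
        defined[s:s + chunk] = inband > POWER_FLOOR * np.maximum(total, 1e-300)
        df[s:s + chunk] = f[sel][np.argmax(pin, axis=-1)]
    return df.reshape(x.shape[:-1]), defined.reshape(x.shape[:-1])


def dominant_frequency(signal: np.ndarray, rate: float,
                       band: tuple[float, float] = DF_BAND) -> float:
    """DF (Hz) of one sampled signal, or NaN when undefined (no in-band
    power, e.g. a quiescent trace)."""
    x = np.asarray(signal, dtype=float)
    df, defined = _welch_df(x[None, :], rate, band)
    return float(df[0]) if defined[0] else float("nan")


@dataclass
class DFMap:
    """Per-node dominant frequency over an analysis window."""

    node_df: np.ndarray           # Hz, NaN where undefined; aligned with nodes
    nodes: np.ndarray             # flat node indices
    window: tuple[float, float]   # ms
    resolution: float             # Hz (spectral bin spacing)

    @property
    def mean_df(self) -> float:
        """Arithmetic mean over defined nodes (NaN if none)."""
        d = self.node_df[np.isfinite(self.node_df)]
        return float(d.mean()) if d.size else float("nan")

    def on_grid(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.full(shape[0] * shape[1], np.nan)
        out[self.nodes] = self.node_df
        return out.reshape(shape)


def df_map(record: SimulationRecord, window: tuple[float, float] | None = None,
           band: tuple[float, float] = DF_BAND) -> DFMap:
    """DF of every recorded, non-ablated node over ``window``.

    Nodes without any activation in the window, and ablated nodes, are
    undefined (NaN).
    """
    if window is None:
        window = (0.0, record.duration)
    lo, hi = window
    if lo < 0 or hi > record.duration + 1e-9:
        raise ValueError("window outside the recorded episode")
    sel = (record.t_samp >= lo) & (record.t_samp < hi)
    x = record.vm[:, sel].astype(float)
    rate = record.sample_rate_hz
    df, defined = _welch_df(x, rate, band)
    # nodes with no activation in the window are undefined by definition
    for k, node in enumerate(record.rec_nodes):
        acts = record.activations(int(node))
        if not np.any((acts >= lo) & (acts < hi)):
            defined[k] = False
    defined &= ~record.ablated[record.rec_nodes]
    out = np.where(defined, df, np.nan)
    nperseg = min(x.shape[-1], int(round(WELCH_SEG_S * rate)))
    nfft = max(nperseg, int(np.ceil(rate / DF_RESOLUTION)))
    return DFMap(out, record.rec_nodes.copy(), window, rate / nfft)


def restitution_pairs(record: SimulationRecord, node: int,
                      window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """(DI, APD90) pairs at one node inside ``window``.

    ``DI_n = activation_n - repol90_{n-1}``; ``APD_n = repol90_n - activation_n``.
    """
    lo, hi = window
    a = record.activations(node)
    r = record.repolarizations(node)
    n = min(a.size, r.size)
    a, r = a[:n], r[:n]
    di, apd = [], []
    for k in range(1, n):
        if not (lo <= a[k] < hi):
            continue
        d = a[k] - r[k - 1]
        ap = r[k] - a[k]
        if d > 0 and ap > 0:
            di.append(d)
            apd.append(ap)
    return np.asarray(di), np.asarray(apd)


def _max_fd_slope(di: np.ndarray, apd: np.ndarray,
                  bin_ms: float = 5.0) -> float:
    """Maximum robust finite-difference slope (fallback estimator).

    Pairs are binned by DI (median DI and median APD per bin) before
    differencing, which tames beat-to-beat noise; on noiseless linear data
    the binned medians lie exactly on the line, so the slope is exact.
    """
    order = np.argsort(di)
    d, a = di[order], apd[order]
    edges = np.arange(d[0], d[-1] + bin_ms, bin_ms)
    idx = np.searchsorted(edges, d, side="right")
    dm, am = [], []
    for b in np.unique(idx):
        sel = idx == b
        dm.append(np.median(d[sel]))
        am.append(np.median(a[sel]))
    dm, am = np.asarray(dm), np.asarray(am)
    dd = np.diff(dm)
    ok = dd > 1e-9
    if not ok.any():
        return 0.0
    slopes = np.diff(am)[ok] / dd[ok]
    return float(max(slopes.max(), 0.0))


_TAU_MAX = 1000.0
_TAU_MIN = 2.0


def _exp_lls(di: np.ndarray, apd: np.ndarray, taus: np.ndarray):
    """Profile least squares for ``APD = A - B exp(-DI/tau)``.

    For fixed tau the model is linear in (A, B); this solves that 2x2
    problem in closed form for every tau at once and returns (A, B, RSS)
    arrays.
    """
    n = di.size
    e = np.exp(-di[:, None] / taus[None, :])          # (n, m)
    s_e = e.sum(axis=0)
    s_ee = (e * e).sum(axis=0)
    s_y = apd.sum()
    s_yy = float(apd @ apd)
    s_ye = apd @ e
    var_e = s_ee - s_e ** 2 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        B = (s_e * s_y / n - s_ye) / var_e
    B = np.where(var_e > 1e-30, B, 0.0)
    A = (s_y + B * s_e) / n
    rss = (s_yy - 2 * A * s_y + 2 * B * s_ye + A ** 2 * n
           - 2 * A * B * s_e + B ** 2 * s_ee)
    return A, B, rss


def fit_smax(di: np.ndarray, apd: np.ndarray) -> tuple[float, dict]:
    """Smax of one node's restitution pairs.

    Primary: least-squares fit of ``APD = A - B exp(-DI/tau)`` (the model
    is linear in A and B given tau, so tau is profiled over a log grid and
    refined by bounded scalar minimization); Smax is the fitted derivative
    ``(B/tau) exp(-DI/tau)`` at the smallest observed DI.  The fit is
    declared failed — and the maximum robust finite-difference slope used
    instead — when the family degenerates (tau at its bound, i.e. an
    effectively linear curve; non-positive B; flat data).
    """
    info: dict = {"method": "fit"}
    if np.ptp(apd) < 1e-9:   # flat restitution carries no slope signal
        info["method"] = "fd"
        return _max_fd_slope(di, apd), info
    taus = np.geomspace(_TAU_MIN, _TAU_MAX, 50)
    A, B, rss = _exp_lls(di, apd, taus)
    valid = B > 0
    if not valid.any():
        info["method"] = "fd"
        return _max_fd_slope(di, apd), info
    rss = np.where(valid, rss, np.inf)
    k = int(np.argmin(rss))
    lo = taus[max(k - 1, 0)]
    hi = taus[min(k + 1, taus.size - 1)]
    from scipy.optimize import minimize_scalar
    r = minimize_scalar(
        lambda t: float(_exp_lls(di, apd, np.array([t]))[2][0]),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4 * taus[k]})
    tau = float(r.x)
    Af, Bf, _ = _exp_lls(di, apd, np.array([tau]))
    Af, Bf = float(Af[0]), float(Bf[0])
    if tau >= 0.95 * _TAU_MAX or Bf <= 1e-9:
        info["method"] = "fd"
        return _max_fd_slope(di, apd), info
    smax = Bf / tau * np.exp(-di.min() / tau)
    info.update(A=Af, B=Bf, tau=tau)
    return max(float(smax), 0.0), info


@dataclass
class RestitutionSet:
    """Per-node restitution analysis over an analysis window."""

    node_smax: np.ndarray       # NaN where not fitted (too few pairs)
    n_pairs: np.ndarray
    window: tuple[float, float]
    min_pairs: int = 5
    fit_info: dict = field(default_factory=dict)

    @property
    def mean_smax(self) -> float:
        s = self.node_smax[np.isfinite(self.node_smax)]
        return float(s.mean()) if s.size else float("nan")


def restitution_smax(record: SimulationRecord,
                     window: tuple[float, float] | None = None,
                     min_pairs: int = 5, node_stride: int = 1) -> RestitutionSet:
    """Restitution Smax per node (nodes with fewer than ``min_pairs``
    (DI, APD) pairs are skipped); warns when no node can be fitted."""
    if window is None:
        window = (0.0, record.duration)
    n = record.act_t.shape[0]
    smax = np.full(n, np.nan)
    npairs = np.zeros(n, dtype=np.int32)
    nodes = np.flatnonzero(~record.ablated)[::node_stride]
    for i in nodes:
        di, apd = restitution_pairs(record, int(i), window)
        npairs[i] = di.size
        if di.size >= min_pairs:
            smax[i], _ = fit_smax(di, apd)
    rs = RestitutionSet(smax, npairs, window, min_pairs)
    if not np.isfinite(smax).any():
        warnings.warn("no node had enough restitution pairs; Smax undefined")
    return rs


def afcl(record: SimulationRecord,
         window: tuple[float, float] | None = None) -> float:
    """AF cycle length (ms): mean inter-activation interval pooled over
    non-ablated nodes within the window; NaN when no intervals exist."""
    if window is None:
        window = (0.0, record.duration)
    lo, hi = window
    total, count = 0.0, 0
    for i in np.flatnonzero(~record.ablated):
        a = record.activations(int(i))
        a = a[(a >= lo) & (a < hi)]
        if a.size >= 2:
            iv = np.diff(a)
            total += iv.sum()
            count += iv.size
    return total / count if count else float("nan")


OUTCOMES = ("AF", "AT", "terminated")
AT_INTERVAL_CV = 0.10       # interval regularity threshold
AT_NODE_FRACTION = 0.90     # fraction of active nodes that must be regular
AT_DF_SPATIAL_SD = 0.5      # Hz
SILENCE_MS = 1000.0         # terminal silence defining termination


def classify_outcome(record: SimulationRecord,
                     window: tuple[float, float] | None = None,
                     band: tuple[float, float] = DF_BAND,
                     dfm: "DFMap | None" = None) -> str:
    """Episode outcome over the final analysis window (default: last 6 s).

    ``terminated``: no activation anywhere during the final second.
    ``AT``: at >= 90% of active nodes the inter-activation-interval
    coefficient of variation is < 0.10 and the spatial SD of node DF is
    < 0.5 Hz (organized, regular activity).  Otherwise ``AF``.
    """
    if window is None:
        window = (max(0.0, record.duration - 6000.0), record.duration)
    lo, hi = window
    if hi > record.duration + 1e-9 or hi - lo <= 0:
        raise ValueError("record shorter than the requested window")

    t_silence = record.duration - SILENCE_MS
    nodes = np.flatnonzero(~record.ablated)
    any_late = any(
        record.n_act[i] and record.activations(int(i))[-1] >= t_silence
        for i in nodes)
    if not any_late:
        return "terminated"

    cvs = []
    for i in nodes:
        a = record.activations(int(i))
        a = a[(a >= lo) & (a < hi)]
        if a.size >= 3:
            iv = np.diff(a)
            cvs.append(iv.std() / iv.mean())
    if not cvs:
        return "terminated"
    regular = np.mean(np.asarray(cvs) < AT_INTERVAL_CV)

    if dfm is None:
        dfm = df_map(record, window, band)
    d = dfm.node_df[np.isfinite(dfm.node_df)]
    df_sd = d.std() if d.size else np.inf

    if regular >= AT_NODE_FRACTION and df_sd < AT_DF_SPATIAL_SD:
        return "AT"
    return "AF"


@dataclass
class EpisodeResult:
    """Wave-dynamics summary of one episode."""

    outcome: str
    mean_df: float        # Hz
    mean_smax: float
    afcl_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")

    @property
    def defragmented(self) -> bool:
        return self.outcome != "AF"


def analyze_episode(record: SimulationRecord,
                    window: tuple[float, float],
                    band: tuple[float, float] = DF_BAND,
                    smax_stride: int = 1,
                    smax_window: tuple[float, float] | None = None,
                    meta: dict | None = None) -> EpisodeResult:
    """DF map mean, mean Smax, AFCL and outcome of one episode.

    All metrics default to the analysis ``window``; ``smax_window`` lets
    restitution pairs be collected over a different span (e.g. the
    induction ramp, which doubles as a pacing-down restitution protocol).
    """
    dfm = df_map(record, window, band)
    if smax_window is None:
        smax_window = window
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rs = restitution_smax(record, smax_window, node_stride=smax_stride)
    out = classify_outcome(record, window, band, dfm=dfm)
    return EpisodeResult(out, dfm.mean_df, rs.mean_smax,
                         afcl(record, window), dict(meta or {}))
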