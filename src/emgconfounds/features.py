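"""Per-channel window features and the named feature sets used in myoelectric
control (TD, TDAR, TSTD, LSF4, LSF9, TDPSD, Hjorth).

Conventions (the literature names these features but rarely pins one formula;
the definitions below are the package's fixed, testable conventions):

==========  ==================================================================
MAV         mean(|x|)
IEMG        sum(|x|)
RMS         sqrt(mean(x^2))
VAR         sum((x - mean)^2) / (n - 1)
WL          sum(|diff(x)|)                    (waveform length)
DASDV       sqrt(mean(diff(x)^2))
MAVFD       MAV of diff(x)
MFL         log10(sqrt(sum(diff(x)^2)))       (maximum fractal length)
MSR         mean(sqrt(|x|))                   (mean square-root amplitude)
LS          second L-moment (L-scale) of the raw window
ZC          count of sign changes with |x_i - x_{i+1}| > threshold
SSC         count of slope-sign changes with threshold
WAMP        count of |diff(x)| > threshold    (Willison amplitude)
ACT         variance (Hjorth activity)
MOB         sqrt(var(diff(x)) / var(x))       (Hjorth mobility)
COMP        MOB(diff(x)) / MOB(x)             (Hjorth complexity)
AR4         Yule-Walker AR coefficients, order 4, biased autocovariance
SampEn      m = 2, r = 0.2 * SD, Chebyshev distance, tolerance "<= r",
            natural log, self-matches excluded
TDPSD       six time-domain power-spectral descriptors (see ``tdpsd``)
==========  ==================================================================

Degenerate windows (zero variance, silent no-motion data) never yield
non-finite values: SampEn, MOB and COMP fall back to 0, and log-domain
quantities clamp their arguments at a small epsilon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.spatial.distance import cdist

from .preprocess import WindowSet

__all__ = [
    "FeatureMatrix",
    "FeatureSetSpec",
    "FEATURE_SETS",
    "extract_feature",
    "extract_set",
    "list_features",
    "get_feature_set",
]

log = logging.getLogger(__name__)

_EPS = 1e-12

# Count of log-argument clamps performed (non-positive m0-m2 / m0-m4 etc.);
# exposed for diagnostics and reset by tests as needed.
clamp_count = 0


def _count_clamp(n: int) -> None:
    global clamp_count
    if n:
        clamp_count += n
        log.debug("clamped %d non-positive log arguments", n)


def _log_clamped(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    mag = np.abs(v)
    _count_clamp(int(np.count_nonzero(mag < _EPS)))
    return np.log(np.maximum(mag, _EPS))


# ---------------------------------------------------------------------------
# scalar features (all operate along the last axis and broadcast over windows)

def mav(x):
    return np.mean(np.abs(x), axis=-1)


def iemg(x):
    return np.sum(np.abs(x), axis=-1)


def rms(x):
    return np.sqrt(np.mean(np.square(x), axis=-1))


def var(x):
    return np.var(x, axis=-1, ddof=1)


def wl(x):
    return np.sum(np.abs(np.diff(x, axis=-1)), axis=-1)


def dasdv(x):
    return np.sqrt(np.mean(np.square(np.diff(x, axis=-1)), axis=-1))


def mavfd(x):
    return np.mean(np.abs(np.diff(x, axis=-1)), axis=-1)


def mfl(x):
    s = np.sqrt(np.sum(np.square(np.diff(x, axis=-1)), axis=-1))
    _count_clamp(int(np.count_nonzero(s < _EPS)))
    return np.log10(np.maximum(s, _EPS))


def msr(x):
    return np.mean(np.sqrt(np.abs(x)), axis=-1)


def ls(x):
    """Second L-moment (L-scale) of the raw window."""
    x = np.sort(np.asarray(x, dtype=float), axis=-1)
    n = x.shape[-1]
    i = np.arange(n)
    b0 = np.mean(x, axis=-1)
    b1 = np.sum(x * i, axis=-1) / (n * (n - 1))
    return 2.0 * b1 - b0


def zc(x, threshold=0.0):
    x = np.asarray(x, dtype=float)
    a, b = x[..., :-1], x[..., 1:]
    crossing = (a * b) < 0
    big = np.abs(a - b) > threshold
    return np.sum(crossing & big, axis=-1).astype(float)


def ssc(x, threshold=0.0):
    x = np.asarray(x, dtype=float)
    prev, mid, nxt = x[..., :-2], x[..., 1:-1], x[..., 2:]
    turning = (mid - prev) * (mid - nxt) > 0
    big = np.maximum(np.abs(mid - prev), np.abs(mid - nxt)) > threshold
    return np.sum(turning & big, axis=-1).astype(float)


def wamp(x, threshold=0.02):
    return np.sum(np.abs(np.diff(x, axis=-1)) > threshold, axis=-1).astype(float)


def act(x):
    return np.var(x, axis=-1)


def mob(x):
    v0 = np.var(x, axis=-1)
    v1 = np.var(np.diff(x, axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(np.divide(v1, v0, out=np.zeros_like(np.asarray(v0, dtype=float)),
                                where=v0 > 0))
    return out


def comp(x):
    m1 = mob(np.diff(x, axis=-1))
    m0 = mob(x)
    return np.divide(m1, m0, out=np.zeros_like(np.asarray(m0, dtype=float)), where=m0 > 0)


# ---------------------------------------------------------------------------
# vector features

def ar4(x, order=4):
    """Yule-Walker autoregressive coefficients (x_t ~ sum a_k x_{t-k}),
    estimated from the biased autocovariance; zero-variance windows give
    all-zero coefficients."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]
    if n < order + 1:
        raise ValueError(f"AR({order}) needs at least {order + 1} samples")
    out = np.zeros(x.shape[:-1] + (order,))
    flat = x.reshape(-1, n)
    oflat = out.reshape(-1, order)
    for i, row in enumerate(flat):
        row = row - row.mean()
        r = np.array([row[: n - k] @ row[k:] for k in range(order + 1)]) / n
        if r[0] <= 0:
            continue
        oflat[i] = solve_toeplitz((r[:order], r[:order]), r[1 : order + 1])
    return out[0] if squeeze else out


def sampen(x, m=2, r_factor=0.2):
    """Sample entropy; 0 on zero-variance windows, and a count floor of one
    m+1-template match keeps the value finite on highly regular windows."""
    x = np.asarray(x, dtype=float)
    if x.ndim > 1:
        return np.apply_along_axis(lambda row: sampen(row, m, r_factor), -1, x)
    n = x.size
    if n < m + 2:
        raise ValueError("window too short for sample entropy")
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_factor * sd
    n_templates = n - m
    xm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    xm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    b = np.count_nonzero(cdist(xm, xm, "chebyshev") <= r) - n_templates
    if b <= 0:
        return 0.0
    a_full = cdist(xm1, xm1, "chebyshev") <= r
    a = np.count_nonzero(a_full) - xm1.shape[0]
    a = max(a, 1)
    return float(-np.log(a / b))


def tdpsd(x):
    """Six time-domain power-spectral descriptors per channel.

    From the window compute m0 = sqrt(sum x^2), m2 = sqrt(sum dx^2),
    m4 = sqrt(sum ddx^2), each power-rescaled m <- m^0.1 / 0.1, and form

        a1 = log m0
        a2 = log(m0 - m2)
        a3 = log(m0 - m4)
        a4 = log(m0 / sqrt((m0 - m2)(m0 - m4)))     (sparseness)
        a5 = log(m2 / sqrt(m0 m4))                  (irregularity)
        a6 = log(sum|dx| / sum|ddx|)                (waveform-length ratio)

    The same descriptors b are computed from the nonlinearly scaled signal
    log(x^2 + eps), and each pair is fused as f = -2ab / (a^2 + b^2).
    Log arguments are clamped (in magnitude) at eps.  ``fused=False`` returns
    the raw descriptors a only.
    """
    return _tdpsd_impl(x, fused=True)


def tdpsd_raw(x):
    return _tdpsd_impl(x, fused=False)


def _tdpsd_descriptors(x):
    dx = np.diff(x, axis=-1)
    ddx = np.diff(dx, axis=-1)
    m0 = np.sqrt(np.sum(np.square(x), axis=-1))
    m2 = np.sqrt(np.sum(np.square(dx), axis=-1))
    m4 = np.sqrt(np.sum(np.square(ddx), axis=-1))
    m0, m2, m4 = (np.maximum(m, _EPS) ** 0.1 / 0.1 for m in (m0, m2, m4))
    d02 = m0 - m2
    d04 = m0 - m4
    a1 = _log_clamped(m0)
    a2 = _log_clamped(d02)
    a3 = _log_clamped(d04)
    a4 = _log_clamped(m0 / np.sqrt(np.maximum(np.abs(d02 * d04), _EPS)))
    a5 = _log_clamped(m2 / np.sqrt(np.maximum(m0 * m4, _EPS)))
    wlr = np.sum(np.abs(dx), axis=-1) / np.maximum(np.sum(np.abs(ddx), axis=-1), _EPS)
    a6 = _log_clamped(wlr)
    return np.stack([a1, a2, a3, a4, a5, a6], axis=-1)


def _tdpsd_impl(x, fused=True):
    x = np.asarray(x, dtype=float)
    a = _tdpsd_descriptors(x)
    if not fused:
        return a
    b = _tdpsd_descriptors(np.log(np.square(x) + _EPS))
    denom = np.square(a) + np.square(b)
    return np.divide(-2.0 * a * b, denom, out=np.zeros_like(a), where=denom > 0)


# ---------------------------------------------------------------------------
# catalog and feature sets

_CATALOG: dict[str, dict] = {
    "MAV": {"func": mav, "dims": 1, "params": {}},
    "IEMG": {"func": iemg, "dims": 1, "params": {}},
    "RMS": {"func": rms, "dims": 1, "params": {}},
    "VAR": {"func": var, "dims": 1, "params": {}},
    "WL": {"func": wl, "dims": 1, "params": {}},
    "DASDV": {"func": dasdv, "dims": 1, "params": {}},
    "MAVFD": {"func": mavfd, "dims": 1, "params": {}},
    "MFL": {"func": mfl, "dims": 1, "params": {}},
    "MSR": {"func": msr, "dims": 1, "params": {}},
    "LS": {"func": ls, "dims": 1, "params": {}},
    "ZC": {"func": zc, "dims": 1, "params": {"threshold": 0.0}},
    "SSC": {"func": ssc, "dims": 1, "params": {"threshold": 0.0}},
    "WAMP": {"func": wamp, "dims": 1, "params": {"threshold": 0.02}},
    "ACT": {"func": act, "dims": 1, "params": {}},
    "MOB": {"func": mob, "dims": 1, "params": {}},
    "COMP": {"func": comp, "dims": 1, "params": {}},
    "AR4": {"func": ar4, "dims": 4, "params": {"order": 4}},
    "SampEn": {"func": sampen, "dims": 1, "params": {"m": 2, "r_factor": 0.2}},
    "TDPSD": {"func": tdpsd, "dims": 6, "params": {}},
    "TDPSD_RAW": {"func": tdpsd_raw, "dims": 6, "params": {}},
}


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    members: tuple[str, ...]
    params: dict = None  # per-feature parameter overrides, name -> kwargs

    def __post_init__(self):
        for member in self.members:
            if member not in _CATALOG:
                raise KeyError(f"unknown feature {member!r}")
        object.__setattr__(self, "params", dict(self.params or {}))

    @property
    def dims_per_channel(self) -> int:
        return sum(_CATALOG[m]["dims"] for m in self.members)


FEATURE_SETS: dict[str, FeatureSetSpec] = {
    "TD": FeatureSetSpec("TD", ("MAV", "ZC", "SSC", "WL")),
    "TDAR": FeatureSetSpec("TDAR", ("MAV", "ZC", "SSC", "WL", "AR4")),
    "TSTD": FeatureSetSpec("TSTD", ("MAVFD", "DASDV", "WAMP", "ZC", "MFL", "SampEn", "TDPSD")),
    "LSF4": FeatureSetSpec("LSF4", ("LS", "MFL", "MSR", "WAMP")),
    "LSF9": FeatureSetSpec(
        "LSF9", ("LS", "MFL", "MSR", "WAMP", "ZC", "RMS", "IEMG", "DASDV", "VAR")
    ),
    "TDPSD": FeatureSetSpec("TDPSD", ("TDPSD",)),
    "Hjorth": FeatureSetSpec("Hjorth", ("ACT", "MOB", "COMP")),
}


def get_feature_set(name: str) -> FeatureSetSpec:
    try:
        return FEATURE_SETS[name]
    except KeyError:
        raise KeyError(f"unknown feature set {name!r}") from None


def list_features() -> dict[str, dict]:
    """Catalog of implemented features: output dims and parameter schema."""
    return {name: {"dims": e["dims"], "params": dict(e["params"])} for name, e in _CATALOG.items()}


def extract_feature(window_channel, feature_name: str, **params) -> np.ndarray:
    """Extract one named feature from a single-channel sample sequence; returns
    a 1-D vector (length 1, or 4 for AR4, or 6 for TDPSD)."""
    if feature_name not in _CATALOG:
        raise KeyError(f"unknown feature {feature_name!r}")
    x = np.asarray(window_channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("extract_feature expects a single channel")
    if x.size < 3:
        raise ValueError("window must hold at least 3 samples")
    entry = _CATALOG[feature_name]
    kwargs = {**entry["params"], **params}
    out = np.atleast_1d(np.asarray(entry["func"](x, **kwargs), dtype=float))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite value from feature {feature_name}")
    return out


@dataclass(frozen=True)
class FeatureMatrix:
    """Observations x named features, with the WindowSet metadata carried
    along.  Column names follow ``FEATURE[channel]`` (multi-dimensional
    features append ``_k``)."""

    values: np.ndarray
    feature_names: list
    subject_id: np.ndarray
    motion_label: np.ndarray
    condition_value: np.ndarray
    trial_index: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values and feature_names misaligned")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise FloatingPointError("feature matrix contains non-finite values")
        n = self.values.shape[0]
        for name in ("subject_id", "motion_label", "condition_value", "trial_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"metadata vector {name} misaligned")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[mask],
            feature_names=self.feature_names,
            subject_id=self.subject_id[mask],
            motion_label=self.motion_label[mask],
            condition_value=self.condition_value[mask],
            trial_index=self.trial_index[mask],
        )


def extract_set(windows: WindowSet, spec: FeatureSetSpec | str) -> FeatureMatrix:
    """Extract a named feature set from every window.

    Column order is feature order in the set x channel order; for features with
    several outputs per channel the components are innermost.
    """
    if isinstance(spec, str):
        spec = get_feature_set(spec)
    w = windows.windows  # n x channels x samples
    n, n_ch, _ = w.shape
    blocks, names = [], []
    for member in spec.members:
        entry = _CATALOG[member]
        kwargs = {**entry["params"], **spec.params.get(member, {})}
        dims = entry["dims"]
        try:
            vals = np.asarray(entry["func"](w, **kwargs), dtype=float)
        except FloatingPointError:
            raise
        if dims == 1:
            vals = vals[..., None]  # n x channels x 1
        bad = ~np.isfinite(vals)
        if np.any(bad):
            idx = int(np.argwhere(bad.any(axis=(1, 2)))[0][0])
            raise FloatingPointError(
                f"non-finite {member} value at window index {idx}"
            )
        for ch in range(n_ch):
            for k in range(dims):
                blocks.append(vals[:, ch, k])
                names.append(f"{member}[{ch}]" if dims == 1 else f"{member}_{k + 1}[{ch}]")
    return FeatureMatrix(
        values=np.column_stack(blocks),
        feature_names=names,
        subject_id=np.asarray(windows.subject_id),
        motion_label=np.asarray(windows.motion_label),
        condition_value=np.asarray(windows.condition_value, dtype=object),
        trial_index=np.asarray(windows.trial_index),
    )
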