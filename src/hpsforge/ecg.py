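"""12-lead pseudo-ECG from activation maps.

Transmembrane voltage is reconstructed as a travelling action-potential
template, v(x, t) = V(t - ta(x)), with V from the two-variable
Mitchell-Schaeffer model.  The extracellular potential at each electrode is
the infinite-homogeneous-conductor dipole sum

    phi_e(t) = sum_elements grad v . grad(1 / |x_c - x_e|) * V_elem,

with unit conductivity, linear tetrahedral shape-function gradients and
element centroids x_c.  Limb, augmented and precordial leads follow from
the Wilson central terminal, which enforces the lead identities
I - II + III = 0 and aVR + aVL + aVF = 0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .activation import ActivationMap
from .config import SimulationConfig
from .geometry import BivMesh

LEAD_ORDER = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")
ELECTRODE_ORDER = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class APTemplate:
    """Sampled normalized action-potential waveform."""

    v: np.ndarray
    dt: float  # ms
    provenance: str = "mitchell_schaeffer"

    def __post_init__(self):
        if self.v.min() < -0.05 or self.v.max() > 1.05:
            raise ValueError("AP template must stay within [-0.05, 1.05] normalized units")

    def sample(self, t):
        """v at times t (ms), zero before t=0, resting tail after the record."""
        t = np.asarray(t, dtype=float)
        idx = t / self.dt
        out = np.interp(idx, np.arange(len(self.v)), self.v, left=self.v[0], right=self.v[-1])
        return np.where(t < 0, self.v[0], out)


@dataclass(frozen=True)
class MitchellSchaefferParams:
    """Published two-variable model constants (ms)."""

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 150.0
    v_gate: float = 0.13


def ms_action_potential(
    params: MitchellSchaefferParams | None = None,
    dt: float = 0.05,
    duration: float = 400.0,
    stimulus: float = 0.8,
    stim_duration: float = 1.0,
) -> APTemplate:
    """Integrate the Mitchell-Schaeffer model from rest with a t=0 stimulus.

    Explicit Euler at ``dt``; a step-halving check rejects step sizes whose
    halving changes the trace materially (the caller must then lower dt).
    ``stimulus`` is the applied current density (1/ms); 0 leaves the cell
    at rest, and the default drives the normalized upstroke to ~1.
    """
    params = params or MitchellSchaefferParams()
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    v = _integrate_ms(params, dt, duration, stimulus, stim_duration)
    v_half = _integrate_ms(params, dt / 2, duration, stimulus, stim_duration)[::2]
    m = min(len(v), len(v_half))
    if np.max(np.abs(v[:m] - v_half[:m])) > 0.05:
        raise ValueError(f"dt={dt} ms too large for a stable Mitchell-Schaeffer integration")
    return APTemplate(np.clip(v, -0.05, 1.05), dt)


def _integrate_ms(params, dt, duration, stimulus, stim_duration):
    n = int(round(duration / dt)) + 1
    v = np.empty(n)
    vv, hh = 0.0, 1.0
    for i in range(n):
        v[i] = vv
        t = i * dt
        j_stim = stimulus if t < stim_duration else 0.0
        dv = hh * vv * vv * (1 - vv) / params.tau_in - vv / params.tau_out + j_stim
        dh = (1 - hh) / params.tau_open if vv < params.v_gate else -hh / params.tau_close
        vv = vv + dt * dv
        hh = min(1.0, max(0.0, hh + dt * dh))
        vv = min(1.05, max(-0.05, vv))
    return v


def analytic_upstroke(dt: float = 0.05, duration: float = 400.0, rise_ms: float = 1.0,
                      apd_ms: float = 250.0) -> APTemplate:
    """Fallback tanh upstroke/plateau template with the same interface."""
    t = np.arange(0, duration + dt / 2, dt)
    up = 0.5 * (1 + np.tanh((t - 2 * rise_ms) / rise_ms))
    down = 0.5 * (1 - np.tanh((t - apd_ms) / (10 * rise_ms)))
    return APTemplate(np.clip(up * down, -0.05, 1.05), dt, "analytic_upstroke")


# ------------------------------------------------------------------ electrodes


@dataclass
class ElectrodeSet:
    """Nine electrode positions (mm): RA, LA, LL, V1..V6."""

    positions: dict

    def __post_init__(self):
        missing = set(ELECTRODE_ORDER) - set(self.positions)
        if missing:
            raise ValueError(f"missing electrodes: {sorted(missing)}")
        pts = np.array([self.positions[k] for k in ELECTRODE_ORDER])
        if len(np.unique(np.round(pts, 6), axis=0)) != len(pts):
            raise ValueError("electrode positions must be pairwise distinct")

    def array(self):
        return np.array([self.positions[k] for k in ELECTRODE_ORDER], dtype=float)


def default_electrodes(mesh: BivMesh, scale: float = 3.0) -> ElectrodeSet:
    """Torso-scale electrode layout on a bounding sphere around the heart.

    Limb electrodes sit far on a frontal-plane triangle; V1..V6 sweep
    around the anterior chest (+x toward the RV).  Positions are synthetic
    plumbing — only their geometric plausibility matters.
    """
    c = mesh.nodes.mean(axis=0)
    r = scale * float(np.linalg.norm(mesh.nodes - c, axis=1).max())
    pos = {
        "RA": c + r * np.array([0.3, -0.9, 0.8]),
        "LA": c + r * np.array([-0.6, -0.7, 0.8]),
        "LL": c + r * np.array([-0.5, -0.3, -1.2]),
    }
    angles = np.radians([80, 60, 40, 20, 0, -20])
    for name, a in zip(("V1", "V2", "V3", "V4", "V5", "V6"), angles):
        pos[name] = c + 0.6 * r * np.array([np.cos(a), -np.sin(a) * 0.6, -0.1]) \
            + 0.6 * r * np.array([0, -0.6, 0])
    return ElectrodeSet(pos)


@dataclass
class ECG12:
    """12-lead trace (rows ordered as LEAD_ORDER) with processing provenance."""

    leads: np.ndarray       # (12, T)
    sample_rate: float      # Hz
    electrodes: ElectrodeSet | None = None
    processing_log: list = field(default_factory=list)

    @property
    def t_ms(self):
        return np.arange(self.leads.shape[1]) * 1000.0 / self.sample_rate

    def lead(self, name):
        return self.leads[LEAD_ORDER.index(name)]

    def copy(self):
        return ECG12(self.leads.copy(), self.sample_rate, self.electrodes,
                     list(self.processing_log))


# ------------------------------------------------------------------- forward


def _element_gradients(mesh: BivMesh):
    """Per-element shape-function gradient operator G (E, 3, 4) and volumes."""
    n = mesh.nodes
    e = mesh.elements
    a, b, c, d = n[e[:, 0]], n[e[:, 1]], n[e[:, 2]], n[e[:, 3]]
    j = np.stack([b - a, c - a, d - a], axis=2)  # (E, 3, 3)
    detj = np.linalg.det(j)
    vol = np.abs(detj) / 6.0
    jinv = np.linalg.inv(j)  # rows: grad of local coords
    g_local = jinv.transpose(0, 2, 1)  # (E, 3, 3): columns grads of N1..N3
    g = np.empty((len(e), 3, 4))
    g[:, :, 1:] = g_local
    g[:, :, 0] = -g_local.sum(axis=2)
    return g, vol


def pseudo_ecg_12lead(
    act: ActivationMap,
    mesh: BivMesh,
    tmpl: APTemplate,
    electrodes: ElectrodeSet,
    sim: SimulationConfig,
) -> ECG12:
    """Dipole-sum pseudo-ECG over the configured recording window.

    Elements containing a node with no finite activation time are excluded
    (with a log entry); an electrode inside the myocardial bounding sphere
    of any element is rejected.
    """
    ta = act.tissue_times
    g, vol = _element_gradients(mesh)
    elem = mesh.elements
    finite = np.isfinite(ta[elem]).all(axis=1)
    log = []
    if not finite.all():
        log.append(f"excluded {int((~finite).sum())} elements with unreached nodes")
    g, vol, elem = g[finite], vol[finite], elem[finite]
    centroids = mesh.nodes[elem].mean(axis=1)

    epos = electrodes.array()
    d2mesh = np.linalg.norm(mesh.nodes[:, None, :] - epos[None, :, :], axis=2).min(axis=0)
    if np.any(d2mesh < 1e-6):
        raise ValueError("electrode lies on/inside the myocardial mesh")
    for k, name in enumerate(ELECTRODE_ORDER):
        inside = np.linalg.norm(centroids - epos[k], axis=1) < mesh.target_edge_length
        if inside.any():
            raise ValueError(f"electrode {name} lies inside the myocardium")

    # lead-field of each electrode: grad(1/R) at the element centroid
    lead_vec = np.empty((len(epos), len(elem), 3))
    for k in range(len(epos)):
        rvec = centroids - epos[k]
        rr = np.linalg.norm(rvec, axis=1)
        lead_vec[k] = -rvec / rr[:, None] ** 3  # grad_x (1/|x - x_e|)

    n_samp = int(round(sim.duration * sim.sample_rate / 1000.0))
    tgrid = np.arange(n_samp) * 1000.0 / sim.sample_rate
    phi = np.zeros((len(epos), n_samp))
    ta_e = ta[elem]  # (E, 4)
    chunk = 32
    for s in range(0, n_samp, chunk):
        tt = tgrid[s : s + chunk]
        vv = tmpl.sample(tt[None, None, :] - ta_e[:, :, None])  # (E, 4, Tc)
        grad = np.einsum("eij,ejt->eit", g, vv)  # (E, 3, Tc)
        phi[:, s : s + chunk] = np.einsum("kei,eit,e->kt", lead_vec, grad, vol)

    e = {name: phi[k] for k, name in enumerate(ELECTRODE_ORDER)}
    wct = (e["RA"] + e["LA"] + e["LL"]) / 3.0
    leads = np.vstack(
        [
            e["LA"] - e["RA"],
            e["LL"] - e["RA"],
            e["LL"] - e["LA"],
            e["RA"] - (e["LA"] + e["LL"]) / 2.0,
            e["LA"] - (e["RA"] + e["LL"]) / 2.0,
            e["LL"] - (e["RA"] + e["LA"]) / 2.0,
        ]
        + [e[f"V{i}"] - wct for i in range(1, 7)]
    )
    return ECG12(leads, sim.sample_rate, electrodes, log)


# -------------------------------------------------------------- postprocessing


def _lowpass(leads, fs, cutoff_hz):
    b, a = signal.butter(4, cutoff_hz / (fs / 2), btype="low")
    return signal.filtfilt(b, a, leads, axis=-1)


def measured_data_filter(leads, fs):
    """The clinical measured-ECG chain: 50 Hz notch, 0.5 Hz high-pass, 60 Hz low-pass."""
    bn, an = signal.iirnotch(50.0, Q=30.0, fs=fs)
    out = signal.filtfilt(bn, an, leads, axis=-1)
    bh, ah = signal.butter(2, 0.5 / (fs / 2), btype="high")
    out = signal.filtfilt(bh, ah, out, axis=-1)
    return _lowpass(out, fs, 60.0)


def postprocess_ecg(
    sim_ecg: ECG12, reference: ECG12 | None = None, lowpass_hz: float = 60.0
) -> ECG12:
    """Zero-phase low-pass, then optional alignment/uniform scaling to a reference.

    Alignment is one global integer sample shift maximizing the summed
    cross-correlation over all 12 leads; scaling is one amplitude factor,
    uniform across leads, minimizing the total squared error.  Both are
    recorded in the processing log.
    """
    out = sim_ecg.copy()
    out.leads = _lowpass(out.leads, out.sample_rate, lowpass_hz)
    out.processing_log.append(f"lowpass {lowpass_hz} Hz (zero-phase)")
    if reference is None:
        return out
    ref = reference
    if ref.sample_rate != out.sample_rate:
        n_new = int(round(ref.leads.shape[1] * out.sample_rate / ref.sample_rate))
        ref = ECG12(signal.resample(ref.leads, n_new, axis=1), out.sample_rate)
    total = np.zeros(out.leads.shape[1] + ref.leads.shape[1] - 1)
    for k in range(12):
        total += signal.correlate(ref.leads[k], out.leads[k], mode="full")
    shift = int(np.argmax(total)) - (out.leads.shape[1] - 1)
    out.leads = _apply_shift(out.leads, shift, ref.leads.shape[1])
    denom = float(np.sum(out.leads**2))
    if denom < 1e-30:
        out.processing_log.append("scaling skipped: zero-variance trace")
        scale = 1.0
    else:
        scale = float(np.sum(ref.leads * out.leads) / denom)
        out.leads = out.leads * scale
    out.processing_log.append(f"aligned shift={shift} samples, uniform scale={scale:.6g}")
    return out


def _apply_shift(leads, shift, n_out):
    out = np.zeros((leads.shape[0], n_out))
    for k in range(leads.shape[0]):
        idx = np.arange(n_out) - shift
        valid = (idx >= 0) & (idx < leads.shape[1])
        out[k, valid] = leads[k, idx[valid]]
    return out


def compare_ecg(a: ECG12, b: ECG12):
    """Per-lead Pearson r and RMSE plus their means.

    Returns {"per_lead": {lead: {"r": .., "rmse": ..}}, "mean_r": ..,
    "mean_rmse": ..}.  Traces must have equal length.
    """
    if a.leads.shape != b.leads.shape:
        raise ValueError(f"trace shapes differ: {a.leads.shape} vs {b.leads.shape}")
    per = {}
    for k, name in enumerate(LEAD_ORDER):
        x, y = a.leads[k], b.leads[k]
        sx, sy = x.std(), y.std()
        r = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else np.nan
        per[name] = {"r": r, "rmse": float(np.sqrt(np.mean((x - y) ** 2)))}
    rs = [m["r"] for m in per.values()]
    return {
        "per_lead": per,
        "mean_r": float(np.nanmean(rs)),
        "mean_rmse": float(np.mean([m["rmse"] for m in per.values()])),
    }
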