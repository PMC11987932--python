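"""Inverse problem: from multi-diffusion-time signals to tissue parameters.

The pipeline mirrors the four-step analysis of the imaging method: (i)
preprocessing (pass-through hook), (ii) model selection — the exchange
regime is chosen per protocol from its effective diffusion time, (iii)
removal of blood perfusion by segmented-IVIM extrapolation, and (iv)
bounded multi-start least-squares estimation of (d, vin, Din, Dex, tau_in),
from which cellularity is derived.

Cellularity (cell cross-sections per mm²) assumes spherical cells densely
packed on a face-centred-cubic grid::

    cellularity = 6 vin / ( (2 pi)^(2/3) d² )

with d converted to mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .acquisition import effective_diffusion_time
from .fd_engine import SignalSet
from .forward_models import (
    EXCHANGE_TDIFF_THRESHOLD,
    FIT_BOUNDS,
    INCLUDE_EXCHANGE,
    TissueParams,
    WaveformGPA,
    exchange_regime,
    karger_attenuation,
)

__all__ = [
    "FitResult",
    "SignalModel",
    "remove_perfusion",
    "fit_voxel",
    "fit_map",
    "cellularity_from_fit",
    "PerfusionFitError",
    "IdentifiabilityError",
]

#: IVIM segmentation threshold: b-values at or above this (ms/µm²) are
#: treated as perfusion-free.
B_PERFUSION_CUTOFF = 0.2

_TWO_PI_23 = (2.0 * math.pi) ** (2.0 / 3.0)  # ~3.40503


class PerfusionFitError(ValueError):
    """Perfusion extrapolation impossible on this curve."""


class IdentifiabilityError(ValueError):
    """Signal set cannot constrain the model (e.g. single diffusion time)."""


@dataclass
class FitResult:
    """Outcome of one voxel/ROI fit."""

    params: TissueParams
    cellularity: float
    residual: float  # root-mean-square misfit of the returned solution
    n_starts_used: int
    converged: bool
    seed: int | None
    informative: bool = True

    def to_dict(self) -> dict:
        out = self.params.to_dict()
        out.update(
            cellularity_per_mm2=self.cellularity, residual_rms=self.residual,
            n_starts_used=self.n_starts_used, converged=self.converged,
            informative=self.informative,
        )
        return out


def cellularity_from_fit(d: float, vin: float) -> float:
    """Cell cross-sections per mm² from fitted diameter (µm) and vin.

    ``6 vin / ((2 pi)^(2/3) d²)`` under the densely-packed-spheres
    assumption; monotone increasing in vin, decreasing in d.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    if not 0.0 <= vin <= 1.0:
        raise ValueError("vin must lie in [0, 1]")
    d_mm = d * 1e-3
    return 6.0 * vin / (_TWO_PI_23 * d_mm * d_mm)


def remove_perfusion(b, signals, b_cutoff: float = B_PERFUSION_CUTOFF):
    """Estimate and strip the perfusion (IVIM) contribution from one curve.

    Fits ``ln S`` linearly over the points with ``b >= b_cutoff`` (where the
    pseudo-diffusion pool has fully dephased), extrapolates to the b = 0
    intercept I, sets ``f_IVIM = max(0, 1 - I)`` and rescales the
    perfusion-free points by ``1/(1 - f_IVIM)``.

    Returns ``(f_IVIM, b_corrected, s_corrected)`` where the corrected curve
    keeps only the b >= cutoff points (plus the implicit S(0) = 1).
    """
    b = np.asarray(b, float)
    s = np.asarray(signals, float)
    sel = b >= b_cutoff
    if np.count_nonzero(sel) < 2:
        raise PerfusionFitError(
            f"need at least 2 points with b >= {b_cutoff} ms/µm²"
        )
    if np.any(s[sel] <= 0):
        raise PerfusionFitError("non-positive signals in the mono-exponential tail")
    slope, log_i = np.polyfit(b[sel], np.log(s[sel]), 1)
    intercept = math.exp(log_i)
    if intercept <= 0:
        raise PerfusionFitError("non-positive extrapolated intercept")
    f_ivim = max(0.0, 1.0 - intercept)
    s_corr = s[sel] / (1.0 - f_ivim)
    return f_ivim, b[sel], s_corr


class SignalModel:
    """Composite tissue model over a protocol set, cached for fitting speed.

    Precomputes per-protocol waveform integrals (:class:`WaveformGPA`) so
    each forward evaluation only interpolates the restricted ADC and applies
    the (Kärger or mixture) compartment sum.
    """

    def __init__(self, protocols, exchange_threshold: float = EXCHANGE_TDIFF_THRESHOLD,
                 geometry: str = "sphere"):
        self.protocols = list(protocols)
        self.geometry = geometry
        self._gpa = {p.protocol_id: WaveformGPA(p) for p in self.protocols}
        self._regime = {
            p.protocol_id: exchange_regime(p, exchange_threshold)
            for p in self.protocols
        }
        self.has_long_tdiff = any(
            r == INCLUDE_EXCHANGE for r in self._regime.values()
        )

    def tdiff(self, protocol_id: str) -> float:
        return self._gpa[protocol_id].tdiff

    def predict(self, protocol_id: str, b, d, vin, Din, Dex,
                tau_in=math.inf):
        """Tissue signal (f_IVIM = 0) for one protocol at b-values ``b``."""
        b = np.asarray(b, float)
        gpa = self._gpa[protocol_id]
        adc_in = gpa.adc_restricted(d, Din, self.geometry)
        if (self._regime[protocol_id] == INCLUDE_EXCHANGE
                and np.isfinite(tau_in) and 0.0 < vin < 1.0):
            return karger_attenuation(b, gpa.tdiff, vin, adc_in, Dex, tau_in)
        return vin * np.exp(-b * adc_in) + (1.0 - vin) * np.exp(-b * Dex)

    def predictor(self, keys, fit_tau: bool):
        """Vectorized forward map x -> signals in ``keys`` order.

        Groups the (protocol, b) keys per protocol so each cost evaluation
        does one array-valued model call per protocol.
        """
        order = {}
        for i, (pid, b) in enumerate(keys):
            order.setdefault(pid, ([], []))
            order[pid][0].append(i)
            order[pid][1].append(b)
        groups = [
            (pid, np.asarray(idx, int), np.asarray(bs, float))
            for pid, (idx, bs) in order.items()
        ]
        n = len(keys)

        def f(x):
            d, vin, Din, Dex = x[:4]
            tau = x[4] if fit_tau else math.inf
            out = np.empty(n)
            for pid, idx, bs in groups:
                out[idx] = self.predict(pid, bs, d, vin, Din, Dex, tau)
            return out

        return f

    def predict_set(self, keys, x, fit_tau: bool):
        return self.predictor(keys, fit_tau)(x)


def _gather(signalset: SignalSet, use_b0: bool):
    keys = []
    vals = []
    for (pid, b), s in sorted(signalset.entries.items()):
        if b == 0.0 and not use_b0:
            continue
        keys.append((pid, b))
        vals.append(s)
    return keys, np.asarray(vals)


def fit_voxel(
    signalset: SignalSet,
    protocols,
    n_starts: int = 20,
    seed: int | None = 0,
    model: SignalModel | None = None,
    perfusion_removal: bool = False,
    bounds: dict | None = None,
    d_floor: float = 0.1,
) -> FitResult:
    """Estimate tissue parameters for one voxel/ROI signal set.

    Minimizes the sum of squared differences between the measured normalized
    signals and the composite model, using ``n_starts`` random interior
    initializations (seeded) of a bounded trust-region least-squares solver;
    the lowest-residual solution wins, ties broken by first found.
    ``tau_in`` is fitted only when a long-diffusion-time protocol is present.

    With ``perfusion_removal`` the segmented-IVIM step runs first on each
    protocol's curve; the mean f_IVIM rescales the b >= 0.2 points and only
    those enter the fit (f_IVIM is fixed, not re-fitted).
    """
    model = model or SignalModel(protocols)
    n_tdiff = len({round(model.tdiff(p.protocol_id), 6) for p in model.protocols})
    if n_tdiff < 2:
        raise IdentifiabilityError(
            "need signals at >= 2 distinct effective diffusion times"
        )

    f_ivim = 0.0
    if perfusion_removal:
        working = {}
        fs = []
        for pid in signalset.protocol_ids():
            b, s = signalset.curve(pid)
            nz = b > 0
            f_p, _, _ = remove_perfusion(b[nz], s[nz])
            fs.append(f_p)
        f_ivim = float(np.mean(fs))
        for (pid, b), s in signalset.entries.items():
            if b >= B_PERFUSION_CUTOFF:
                working[(pid, b)] = s / (1.0 - f_ivim)
        signalset = SignalSet(entries=working, s0=signalset.s0,
                              tdiff=dict(signalset.tdiff))

    keys, meas = _gather(signalset, use_b0=False)
    if len(keys) == 0 or not np.all(np.isfinite(meas)) or np.all(meas <= 0):
        raise ValueError("no usable (finite, positive) diffusion-weighted signals")

    fit_tau = model.has_long_tdiff
    bnds = dict(FIT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    names = ["d", "vin", "Din", "Dex"] + (["tau_in"] if fit_tau else [])
    lo = np.array([bnds[n][0] for n in names], float)
    hi = np.array([bnds[n][1] for n in names], float)
    # small positive floors keep the restricted-ADC series and exchange
    # rates away from their singular limits
    floors = {"d": d_floor, "tau_in": 0.2}
    for i, n in enumerate(names):
        lo[i] = max(lo[i], floors.get(n, 0.0))

    forward = model.predictor(keys, fit_tau)

    def residuals(x):
        return forward(x) - meas

    rng = np.random.default_rng(seed)
    best = None
    n_used = 0
    for _ in range(n_starts):
        x0 = rng.uniform(lo + 0.01 * (hi - lo), hi - 0.01 * (hi - lo))
        n_used += 1
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                ftol=1e-8, xtol=1e-6, gtol=1e-8)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    x = best.x
    d, vin, Din, Dex = x[:4]
    tau = float(x[4]) if fit_tau else math.inf
    params = TissueParams(d=float(d), vin=float(vin), Din=float(Din),
                          Dex=float(Dex), tau_in=tau, f_IVIM=f_ivim)
    rms = math.sqrt(2.0 * best.cost / len(meas))
    # flat curves carry no microstructural information: the optimizer parks
    # at a non-decaying corner of the box
    informative = bool(np.ptp(meas) > 1e-6 and np.min(meas) < 0.999)
    return FitResult(
        params=params,
        cellularity=cellularity_from_fit(max(float(d), 1e-6), float(vin)),
        residual=rms,
        n_starts_used=n_used,
        converged=bool(best.success),
        seed=seed,
        informative=informative,
    )


def fit_map(
    stack: np.ndarray,
    keys,
    protocols,
    roi: bool = False,
    n_starts: int = 20,
    seed: int | None = 0,
    model: SignalModel | None = None,
    **fit_kwargs,
):
    """Fit a spatial stack of signal sets.

    ``stack`` has shape ``(..., n_meas)`` with the trailing axis matching
    ``keys`` — a list of ``(protocol_id, b)`` pairs.  With ``roi=True`` the
    signals are averaged over the leading axes before a single fit (SNR
    grows with the square root of the number of voxels averaged); otherwise
    each element is fitted independently and parametric maps are returned
    as a dict of arrays (``d``, ``vin``, ``cellularity``, ``residual``),
    with failed elements masked as NaN.
    """
    model = model or SignalModel(protocols)
    keys = [(pid, round(float(b), 9)) for pid, b in keys]
    tdiff = {p.protocol_id: effective_diffusion_time(p) for p in protocols}

    def one(values, child_seed):
        entries = dict(zip(keys, np.asarray(values, float)))
        ss = SignalSet(entries=entries, s0=1.0, tdiff=tdiff)
        return fit_voxel(ss, protocols, n_starts=n_starts, seed=child_seed,
                         model=model, **fit_kwargs)

    if roi:
        mean = np.asarray(stack, float).reshape(-1, len(keys)).mean(axis=0)
        return one(mean, seed)

    shape = stack.shape[:-1]
    flat = np.asarray(stack, float).reshape(-1, len(keys))
    maps = {k: np.full(flat.shape[0], np.nan)
            for k in ("d", "vin", "Din", "Dex", "cellularity", "residual")}
    ss_seed = np.random.SeedSequence(seed)
    children = ss_seed.spawn(flat.shape[0])
    for i in range(flat.shape[0]):
        child = int(children[i].generate_state(1)[0] % (2 ** 31))
        try:
            r = one(flat[i], child)
        except Exception:
            continue
        maps["d"][i] = r.params.d
        maps["vin"][i] = r.params.vin
        maps["Din"][i] = r.params.Din
        maps["Dex"][i] = r.params.Dex
        maps["cellularity"][i] = r.cellularity
        maps["residual"][i] = r.residual
    return {k: v.reshape(shape) for k, v in maps.items()}


def save_maps(maps: dict, prefix, resolution_um: float | None = None) -> None:
    """Write parametric maps as NIfTI (``<prefix>_<name>.nii.gz``)."""
    import nibabel as nib

    affine = np.eye(4)
    if resolution_um is not None:
        affine[0, 0] = affine[1, 1] = resolution_um * 1e-3
    for name, arr in maps.items():
        img = nib.Nifti1Image(np.asarray(arr, np.float64), affine)
        nib.save(img, f"{prefix}_{name}.nii.gz")
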