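"""Numba kernels for the lattice Bloch-Torrey simulation."""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def evolve(mr, mi, tr, ti, wN, wS, wE, wW, g, dt_over_dx2, gamma_dx_dt, nsteps):
    """Evolve complex magnetization under diffusion + gradient phase.

    ``mr``/``mi`` are (ny+2, nx+2) padded real/imaginary parts; ``tr``/``ti``
    are scratch buffers of the same shape.  ``wN..wW`` are (ny, nx) neighbour
    conductances (diffusivity-equivalent, µm²/ms; already include any
    membrane factor and are zero across the outer boundary via padding).
    ``g[s]`` is the gradient amplitude at step ``s`` (mT/m);
    ``gamma_dx_dt = GAMMA * dx * dt`` converts it to a per-column phase
    increment about the field centre.  Returns the evolved (mr, mi).
    """
    ny, nx = wN.shape
    x0 = 0.5 * (nx - 1)
    for s in range(nsteps):
        gs = g[s]
        # per-column phase increment: theta_j = -gamma * g * (j - x0) * dx * dt
        cosv = np.empty(nx)
        sinv = np.empty(nx)
        for j in range(nx):
            th = -gamma_dx_dt * gs * (j - x0)
            cosv[j] = np.cos(th)
            sinv[j] = np.sin(th)
        for i in range(ny):
            ip = i + 1
            for j in range(nx):
                jp = j + 1
                a = mr[ip, jp]
                b = mi[ip, jp]
                accr = (wN[i, j] * (mr[ip - 1, jp] - a)
                        + wS[i, j] * (mr[ip + 1, jp] - a)
                        + wW[i, j] * (mr[ip, jp - 1] - a)
                        + wE[i, j] * (mr[ip, jp + 1] - a))
                acci = (wN[i, j] * (mi[ip - 1, jp] - b)
                        + wS[i, j] * (mi[ip + 1, jp] - b)
                        + wW[i, j] * (mi[ip, jp - 1] - b)
                        + wE[i, j] * (mi[ip, jp + 1] - b))
                a = a + dt_over_dx2 * accr
                b = b + dt_over_dx2 * acci
                c = cosv[j]
                d = sinv[j]
                tr[ip, jp] = a * c - b * d
                ti[ip, jp] = a * d + b * c
        mr, tr = tr, mr
        mi, ti = ti, mi
    return mr, mi
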