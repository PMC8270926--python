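"""Compiled inner loops of the simulator and the BPTT backward pass.

These kernels implement exactly the same recursions as the pure-NumPy
loops in :mod:`dexat.network` and :mod:`dexat.training` (which remain the
reference path, used for the smooth-spike mode and threshold-noise
injection); an equivalence test pins the two paths to each other.  When
numba is unavailable the package transparently falls back to NumPy.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def forward_kernel(
    xin, w_rec, w_out, alpha, rho1, rho2, beta1, beta2, b0, c1, c2,
    n_ref, kappa, Z, Bth, Y, Vhat, Can,
):
    """Hard-spike forward pass; fills the preallocated time-major traces."""
    T, n_batch, h = xin.shape
    n_out = w_out.shape[1]
    v = np.zeros((n_batch, h))
    b1 = np.zeros((n_batch, h))
    b2 = np.zeros((n_batch, h))
    z = np.zeros((n_batch, h))
    r = np.zeros((n_batch, h), dtype=np.int64)
    y = np.zeros((n_batch, n_out))
    for t in range(T):
        rec = np.dot(z, w_rec)  # recurrent input from the previous step
        for i in range(n_batch):
            for j in range(h):
                b1[i, j] = rho1[j] * b1[i, j] + c1[j] * z[i, j]
                b2[i, j] = rho2[j] * b2[i, j] + c2[j] * z[i, j]
                Bt = b0[j] + beta1[j] * b1[i, j] + beta2[j] * b2[i, j]
                vh = alpha[j] * v[i, j] + xin[t, i, j] + rec[i, j]
                can = r[i, j] == 0
                zn = 1.0 if (can and vh >= Bt) else 0.0
                if zn > 0.0:
                    r[i, j] = n_ref[j]
                elif r[i, j] > 0:
                    r[i, j] -= 1
                v[i, j] = vh - Bt * zn
                z[i, j] = zn
                Z[t, i, j] = zn
                Bth[t, i, j] = Bt
                Vhat[t, i, j] = vh
                Can[t, i, j] = can
        yout = np.dot(z, w_out)
        for i in range(n_batch):
            for k in range(n_out):
                y[i, k] = kappa * y[i, k] + yout[i, k]
                Y[t, i, k] = y[i, k]


@njit(cache=True)
def backward_kernel(
    Z, Bth, Vhat, Can, gm, w_rec_T, w_out_T, alpha, rho1, rho2,
    beta1, beta2, c1, c2, kappa, dampening, gz_rate, GY, GVhat,
):
    """Reverse pass over the recorded traces; fills GY and GVhat."""
    T, n_batch, h = Z.shape
    n_out = gm.shape[2]
    gy = np.zeros((n_batch, n_out))
    gvn = np.zeros((n_batch, h))  # dL/dvhat_{t+1}
    gb1 = np.zeros((n_batch, h))
    gb2 = np.zeros((n_batch, h))
    for t in range(T - 1, -1, -1):
        for i in range(n_batch):
            for k in range(n_out):
                gy[i, k] = gm[t, i, k] + kappa * gy[i, k]
                GY[t, i, k] = gy[i, k]
        gz_syn = np.dot(gy, w_out_T) + np.dot(gvn, w_rec_T)
        for i in range(n_batch):
            for j in range(h):
                gv = alpha[j] * gvn[i, j]
                gz = (
                    gz_syn[i, j]
                    + c1[j] * gb1[i, j]
                    + c2[j] * gb2[i, j]
                    - Bth[t, i, j] * gv
                    + gz_rate[j]
                )
                d = 1.0 - abs(Vhat[t, i, j] - Bth[t, i, j]) / Bth[t, i, j]
                psi = dampening * d if d > 0.0 else 0.0
                if not Can[t, i, j]:
                    psi = 0.0
                gvh = gv + psi * gz
                gB = -psi * gz - Z[t, i, j] * gv
                gb1[i, j] = beta1[j] * gB + rho1[j] * gb1[i, j]
                gb2[i, j] = beta2[j] * gB + rho2[j] * gb2[i, j]
                GVhat[t, i, j] = gvh
                gvn[i, j] = gvh
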