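"""Independent reference implementation of plain KL-NMF for oracle tests.

Standard Lee-Seung multiplicative updates for the generalized
KL divergence, with per-iteration unit-sum column normalization of W and
the compensating row rescale of H — no smoothing matrix anywhere.
Written separately from the package so the smoothing-free limit of the
nsNMF solver can be checked against code that never touches it.
"""

import numpy as np

EPS = 1e-12


def plain_kl_nmf_iterates(V, W0, H0, n_iter, checkpoints=(10, 25, 40)):
    """Run n_iter updates, returning {iteration: (W, H)} at checkpoints."""
    W, H = W0.copy(), H0.copy()
    ones = np.ones_like(V)
    out = {}
    for t in range(1, n_iter + 1):
        H *= (W.T @ (V / np.maximum(W @ H, EPS))) / np.maximum(W.T @ ones,
                                                               EPS)
        W *= ((V / np.maximum(W @ H, EPS)) @ H.T) / np.maximum(ones @ H.T,
                                                               EPS)
        col = np.maximum(W.sum(axis=0), EPS)
        W /= col
        H *= col[:, None]
        if t in checkpoints:
            out[t] = (W.copy(), H.copy())
    return out
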