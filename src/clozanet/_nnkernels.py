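"""Numba kernels for the sparse multimodal network.

The network's sparsity makes its weights naturally dense *per group*: input
i owns a dedicated column of K first-layer nodes, so the first layer is a
(D, K) elementwise map rather than a (D, D*K) matrix, and each first-layer
node has exactly one outgoing weight to its block's second-layer node.  All
kernels operate on these compact arrays:

  W1, b1 : (D, K)  input i -> its K dedicated hidden nodes
  W2     : (D, K)  hidden node (i, k) -> second-layer node of block(i)
  b2     : (B,)    second-layer biases
  w3, b3 : (B,), scalar  second layer -> output node
  block_of : (D,) int  block index of each input

Only these non-zero weights exist; the structural zeros of the full
(dense-equivalent) weight matrices are never materialized, so they trivially
stay zero through training.
"""

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def forward(X, W1, b1, W2, b2, w3, b3, block_of):
    """Forward pass; returns (A1, A2, out) activations for a batch."""
    n, D = X.shape
    K = W1.shape[1]
    B = b2.shape[0]
    A1 = np.empty((n, D, K))
    A2 = np.empty((n, B))
    out = np.empty(n)
    for s in range(n):
        z2 = b2.copy()
        for i in range(D):
            xi = X[s, i]
            bi = block_of[i]
            for k in range(K):
                a = 1.0 / (1.0 + np.exp(-(xi * W1[i, k] + b1[i, k])))
                A1[s, i, k] = a
                z2[bi] += a * W2[i, k]
        z3 = b3
        for b in range(B):
            a2 = 1.0 / (1.0 + np.exp(-z2[b]))
            A2[s, b] = a2
            z3 += a2 * w3[b]
        out[s] = 1.0 / (1.0 + np.exp(-z3))
    return A1, A2, out


@njit(cache=False, fastmath=True)
def loss_and_grads(X, y, W1, b1, W2, b2, w3, b3, block_of):
    """Mean binary cross-entropy and its gradients for one batch."""
    n, D = X.shape
    K = W1.shape[1]
    B = b2.shape[0]
    A1, A2, out = forward(X, W1, b1, W2, b2, w3, b3, block_of)

    loss = 0.0
    for s in range(n):
        p = min(max(out[s], 1e-12), 1.0 - 1e-12)
        loss += -(y[s] * np.log(p) + (1.0 - y[s]) * np.log(1.0 - p))
    loss /= n

    gW1 = np.zeros((D, K))
    gb1 = np.zeros((D, K))
    gW2 = np.zeros((D, K))
    gb2 = np.zeros(B)
    gw3 = np.zeros(B)
    gb3 = 0.0
    dZ2 = np.empty(B)
    for s in range(n):
        d3 = (out[s] - y[s]) / n  # dL/dz3 for sigmoid + BCE
        gb3 += d3
        for b in range(B):
            gw3[b] += A2[s, b] * d3
            a2 = A2[s, b]
            dZ2[b] = d3 * w3[b] * a2 * (1.0 - a2)
            gb2[b] += dZ2[b]
        for i in range(D):
            d2 = dZ2[block_of[i]]
            xi = X[s, i]
            for k in range(K):
                a1 = A1[s, i, k]
                gW2[i, k] += d2 * a1
                dz1 = d2 * W2[i, k] * a1 * (1.0 - a1)
                gb1[i, k] += dz1
                gW1[i, k] += dz1 * xi
    return loss, gW1, gb1, gW2, gb2, gw3, gb3


@njit(cache=False, fastmath=True)
def train_adam(X, y, W1, b1, W2, b2, w3, b3, block_of,
               iterations, batch_size, lr, beta1, beta2, eps,
               seed, log_every):
    """ADAM mini-batch training, in place; returns the logged loss curve.

    Each iteration draws ``batch_size`` distinct rows uniformly at random
    (partial Fisher-Yates), computes BCE gradients and applies one
    bias-corrected ADAM step to every weight group.  The forward/backward
    pass is fused with preallocated buffers; a unit test pins its gradients
    to `loss_and_grads`.
    """
    np.random.seed(seed)
    n = X.shape[0]
    D, K = W1.shape
    B = b2.shape[0]
    nb = batch_size

    mW1 = np.zeros((D, K)); vW1 = np.zeros((D, K))
    mb1 = np.zeros((D, K)); vb1 = np.zeros((D, K))
    mW2 = np.zeros((D, K)); vW2 = np.zeros((D, K))
    mb2 = np.zeros(B); vb2 = np.zeros(B)
    mw3 = np.zeros(B); vw3 = np.zeros(B)
    mb3 = 0.0; vb3 = 0.0

    idx = np.arange(n)
    n_log = iterations // log_every if log_every > 0 else 0
    losses = np.empty(n_log)

    A1 = np.empty((nb, D, K))
    A2 = np.empty((nb, B))
    out = np.empty(nb)
    z2 = np.empty(B)
    dZ2 = np.empty((nb, B))
    gW1 = np.empty((D, K))
    gb1 = np.empty((D, K))
    gW2 = np.empty((D, K))
    gb2 = np.empty(B)
    gw3 = np.empty(B)

    for t in range(1, iterations + 1):
        for j in range(nb):  # partial Fisher-Yates
            r = j + np.random.randint(0, n - j)
            tmp = idx[j]; idx[j] = idx[r]; idx[r] = tmp

        # forward
        loss = 0.0
        for s in range(nb):
            row = idx[s]
            for b in range(B):
                z2[b] = b2[b]
            for i in range(D):
                xi = X[row, i]
                bi = block_of[i]
                acc = 0.0
                for k in range(K):
                    a = 1.0 / (1.0 + np.exp(-(xi * W1[i, k] + b1[i, k])))
                    A1[s, i, k] = a
                    acc += a * W2[i, k]
                z2[bi] += acc
            z3 = b3
            for b in range(B):
                a2 = 1.0 / (1.0 + np.exp(-z2[b]))
                A2[s, b] = a2
                z3 += a2 * w3[b]
            p = 1.0 / (1.0 + np.exp(-z3))
            out[s] = p
            pc = min(max(p, 1e-12), 1.0 - 1e-12)
            ys = y[row]
            loss += -(ys * np.log(pc) + (1.0 - ys) * np.log(1.0 - pc))
        loss /= nb

        # backward
        gb3 = 0.0
        for b in range(B):
            gw3[b] = 0.0
            gb2[b] = 0.0
        for s in range(nb):
            d3 = (out[s] - y[idx[s]]) / nb
            gb3 += d3
            for b in range(B):
                a2 = A2[s, b]
                gw3[b] += a2 * d3
                dZ2[s, b] = d3 * w3[b] * a2 * (1.0 - a2)
                gb2[b] += dZ2[s, b]
        for i in range(D):
            bi = block_of[i]
            for k in range(K):
                g2 = 0.0
                gb = 0.0
                gw = 0.0
                for s in range(nb):
                    a1 = A1[s, i, k]
                    d2 = dZ2[s, bi]
                    g2 += d2 * a1
                    dz1 = d2 * W2[i, k] * a1 * (1.0 - a1)
                    gb += dz1
                    gw += dz1 * X[idx[s], i]
                gW2[i, k] = g2
                gb1[i, k] = gb
                gW1[i, k] = gw

        # ADAM update
        c1 = 1.0 - beta1 ** t
        c2 = 1.0 - beta2 ** t
        for i in range(D):
            for k in range(K):
                mW1[i, k] = beta1 * mW1[i, k] + (1 - beta1) * gW1[i, k]
                vW1[i, k] = beta2 * vW1[i, k] + (1 - beta2) * gW1[i, k] ** 2
                W1[i, k] -= lr * (mW1[i, k] / c1) / (np.sqrt(vW1[i, k] / c2) + eps)
                mb1[i, k] = beta1 * mb1[i, k] + (1 - beta1) * gb1[i, k]
                vb1[i, k] = beta2 * vb1[i, k] + (1 - beta2) * gb1[i, k] ** 2
                b1[i, k] -= lr * (mb1[i, k] / c1) / (np.sqrt(vb1[i, k] / c2) + eps)
                mW2[i, k] = beta1 * mW2[i, k] + (1 - beta1) * gW2[i, k]
                vW2[i, k] = beta2 * vW2[i, k] + (1 - beta2) * gW2[i, k] ** 2
                W2[i, k] -= lr * (mW2[i, k] / c1) / (np.sqrt(vW2[i, k] / c2) + eps)
        for b in range(B):
            mb2[b] = beta1 * mb2[b] + (1 - beta1) * gb2[b]
            vb2[b] = beta2 * vb2[b] + (1 - beta2) * gb2[b] ** 2
            b2[b] -= lr * (mb2[b] / c1) / (np.sqrt(vb2[b] / c2) + eps)
            mw3[b] = beta1 * mw3[b] + (1 - beta1) * gw3[b]
            vw3[b] = beta2 * vw3[b] + (1 - beta2) * gw3[b] ** 2
            w3[b] -= lr * (mw3[b] / c1) / (np.sqrt(vw3[b] / c2) + eps)
        mb3 = beta1 * mb3 + (1 - beta1) * gb3
        vb3 = beta2 * vb3 + (1 - beta2) * gb3 ** 2
        b3 -= lr * (mb3 / c1) / (np.sqrt(vb3 / c2) + eps)

        if log_every > 0 and t % log_every == 0:
            losses[t // log_every - 1] = loss
    return b3, losses
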