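"""Independent straight-line (explicit-loop) reference implementations.

Deliberately framework-free: plain Python loops and scalar math only, so
they share no code path with the package's vectorized/autodiff versions.
"""

import math

import numpy as np


def sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def oracle_channel_shuffle(x, g):
    """Explicit channel permutation via reshape-(g, C/g)-transpose-flatten."""
    c = x.shape[0]
    out = np.empty_like(x)
    k = 0
    for j in range(c // g):        # position within group
        for i in range(g):         # group index
            out[k] = x[i * (c // g) + j]
            k += 1
    return out


def oracle_channel_attention(x, w1, b1, w2, b2):
    """Per-location FC channel attention; returns (Ac, XCA)."""
    c, h, w = x.shape
    cr = w1.shape[0]
    ac = np.zeros_like(x)
    out = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            hid = [max(0.0, sum(w1[r, k] * x[k, i, j] for k in range(c)) + b1[r])
                   for r in range(cr)]
            for k in range(c):
                a = sigmoid(sum(w2[k, r] * hid[r] for r in range(cr)) + b2[k])
                ac[k, i, j] = a
                out[k, i, j] = x[k, i, j] * a
    return ac, out


def oracle_conv(x, weight, bias):
    """Explicit-loop same-padding cross-correlation (odd kernel)."""
    cin, h, w = x.shape
    cout, _, kh, kw = weight.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((cout, h, w))
    for o in range(cout):
        for i in range(h):
            for j in range(w):
                acc = bias[o]
                for c in range(cin):
                    for di in range(kh):
                        for dj in range(kw):
                            si, sj = i + di - ph, j + dj - pw
                            if 0 <= si < h and 0 <= sj < w:
                                acc += weight[o, c, di, dj] * x[c, si, sj]
                out[o, i, j] = acc
    return out


def oracle_spatial_attention(xca, conv1_w, conv1_b, bn_gamma, bn_beta,
                             bn_mean, bn_var, bn_eps, conv2_w, conv2_b, g):
    """f1 -> ReLU -> BN -> f2 -> sigmoid -> shuffle -> gate; returns (As, XSA)."""
    a = oracle_conv(xca, conv1_w, conv1_b)
    a = np.maximum(a, 0.0)
    for c in range(a.shape[0]):
        a[c] = (a[c] - bn_mean[c]) / math.sqrt(bn_var[c] + bn_eps) \
            * bn_gamma[c] + bn_beta[c]
    a = oracle_conv(a, conv2_w, conv2_b)
    a_s = np.vectorize(sigmoid)(a)
    shuffled = oracle_channel_shuffle(a_s, g)
    return a_s, xca * shuffled


def oracle_cam(x, ctx_w, ctx_b, a_w, a_b, ln_gamma, ln_beta, ln_eps,
               b_w, b_b):
    """The seven-step context block: score, softmax, weight, transform, gate."""
    c, h, w = x.shape
    scores = oracle_conv(x, ctx_w, ctx_b)
    weights = np.zeros_like(scores)
    for k in range(c):                       # spatial softmax per channel
        flat = scores[k].ravel()
        e = np.array([math.exp(v - flat.max()) for v in flat])
        weights[k] = (e / e.sum()).reshape(h, w)
    xw = weights * x
    t = oracle_conv(xw, a_w, a_b)
    cb = t.shape[0]
    for i in range(h):                       # layer norm over channels
        for j in range(w):
            v = t[:, i, j]
            mu = v.mean()
            var = ((v - mu) ** 2).mean()
            t[:, i, j] = (v - mu) / math.sqrt(var + ln_eps) * ln_gamma + ln_beta
    gate = np.vectorize(sigmoid)(oracle_conv(t, b_w, b_b))
    return x + gate * xw


def oracle_image_tally(pred, true):
    """Brute-force per-element image-level confusion tally."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred, true):
        if t == "positive" and p == "positive":
            tp += 1
        elif t == "positive":
            fn += 1
        elif p == "positive":
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def oracle_auc_mannwhitney(scores, labels):
    """AUC as the Mann-Whitney U statistic with tie correction."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_ciou(p, g):
    """Independent formula evaluation of the complete-IoU value."""
    ix1, iy1 = max(p[0], g[0]), max(p[1], g[1])
    ix2, iy2 = min(p[2], g[2]), min(p[3], g[3])
    inter = max(0.0, ix2 - ix1) * max(0.0, iy2 - iy1)
    union = ((p[2] - p[0]) * (p[3] - p[1])
             + (g[2] - g[0]) * (g[3] - g[1]) - inter)
    iou = inter / union
    c2 = ((max(p[2], g[2]) - min(p[0], g[0])) ** 2
          + (max(p[3], g[3]) - min(p[1], g[1])) ** 2) + 1e-7
    rho2 = (((p[0] + p[2]) / 2 - (g[0] + g[2]) / 2) ** 2
            + ((p[1] + p[3]) / 2 - (g[1] + g[3]) / 2) ** 2)
    v = 4 / math.pi ** 2 * (
        math.atan((g[2] - g[0]) / (g[3] - g[1]))
        - math.atan((p[2] - p[0]) / (p[3] - p[1]))) ** 2
    alpha = v / (1 - iou + v + 1e-7)
    return iou - rho2 / c2 - alpha * v
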