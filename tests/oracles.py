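"""Independent brute-force oracles for the test suite.

Everything here is deliberately written the slow, obvious way — explicit
loops, naive O(n^2) transforms, generic linear algebra — and shares no
helper code with the package, so agreement between the two code paths is
meaningful evidence of correctness.
"""

import math

import numpy as np


# ---- handcrafted features -------------------------------------------------

def mean_bf(xs):
    return sum(xs) / len(xs)


def std_bf(xs):
    mu = mean_bf(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / (len(xs) - 1))


def zero_crossings_bf(xs):
    count = 0
    prev_sign = 0
    for x in xs:
        s = int(x > 0) - int(x < 0)
        if s == 0:
            s = prev_sign
        if prev_sign != 0 and s != 0 and s != prev_sign:
            count += 1
        if s != 0:
            prev_sign = s
    return count


def percentile_bf(xs, q):
    """Linear interpolation between closest ranks (inclusive definition)."""
    s = sorted(xs)
    pos = (len(s) - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def kurtosis_bf(xs):
    mu = mean_bf(xs)
    sigma = std_bf(xs)
    return sum((x - mu) ** 4 for x in xs) / (len(xs) * sigma**4)


def skewness_bf(xs):
    mu = mean_bf(xs)
    sigma = std_bf(xs)
    return sum((x - mu) ** 3 for x in xs) / (len(xs) * sigma**3)


def autocorr_bf(xs, k):
    mu = mean_bf(xs)
    num = sum((xs[i] - mu) * (xs[i + k] - mu) for i in range(len(xs) - k))
    den = sum((x - mu) ** 2 for x in xs)
    return num / den


def order_mean_bf(xs):
    s = sorted(xs)
    d1 = [s[i + 1] - s[i] for i in range(len(s) - 1)]
    d2 = [d1[i + 1] - d1[i] for i in range(len(d1) - 1)]
    fom = sum(d1) / len(d1)
    norm_fom = sum(abs(d) for d in d1)
    som = sum(d2) / len(d2)
    norm_som = math.sqrt(sum(d * d for d in d2))
    return fom, norm_fom, som, norm_som


def dft_magnitudes_bf(xs):
    """Naive O(n^2) DFT magnitudes over non-negative frequencies."""
    n = len(xs)
    mags = []
    for k in range(n // 2 + 1):
        re = sum(xs[i] * math.cos(-2 * math.pi * k * i / n) for i in range(n))
        im = sum(xs[i] * math.sin(-2 * math.pi * k * i / n) for i in range(n))
        mags.append(math.hypot(re, im))
    return mags


def spectral_energy_bf(xs):
    return sum(m * m for m in dft_magnitudes_bf(xs))


def spectral_entropy_bf(xs):
    mags = dft_magnitudes_bf(xs)
    total = sum(mags)
    ent = 0.0
    for m in mags:
        p = m / total
        if p > 0:
            ent -= p * math.log(p)
    return ent


def all_features_bf(xs, autocorr_lag=1):
    """All 18 features in the package's slot order."""
    p25 = percentile_bf(xs, 25)
    p75 = percentile_bf(xs, 75)
    fom, nfom, som, nsom = order_mean_bf(xs)
    return [
        max(xs), min(xs), mean_bf(xs), std_bf(xs),
        zero_crossings_bf(xs),
        percentile_bf(xs, 20), percentile_bf(xs, 50), percentile_bf(xs, 80),
        p75 - p25,
        kurtosis_bf(xs), skewness_bf(xs), autocorr_bf(xs, autocorr_lag),
        fom, nfom, som, nsom,
        spectral_entropy_bf(xs), spectral_energy_bf(xs),
    ]


# ---- windowing ------------------------------------------------------------

def count_windows_bf(n, w, step):
    """Enumerate window start positions one by one."""
    count = 0
    start = 0
    while start + w <= n:
        count += 1
        start += step
    return count


# ---- LLC ------------------------------------------------------------------

def llc_kkt_bf(x, centers, knn, lam, sigma):
    """Full-support LLC via the KKT system of the equality-constrained QP.

    Selects the knn nearest centers (Euclidean, ties by index), then
    assembles and solves the (knn+1) KKT system of

        min_u ||x - B^T u||^2 + lam * ||d (.) u||^2   s.t.  sum(u) = 1

    entirely with generic dense linear algebra.  Returns the dense
    length-k coefficient vector.
    """
    x = np.asarray(x, float)
    centers = np.asarray(centers, float)
    k = centers.shape[0]
    dists = [float(np.linalg.norm(x - centers[j])) for j in range(k)]
    support = sorted(range(k), key=lambda j: (dists[j], j))[:knn]
    support = sorted(support)
    B = centers[support]
    d = np.array([math.exp(dists[j] / sigma) for j in support])
    # quadratic form: u' (B B' + lam diag(d^2)) u - 2 u' B x + const
    H = np.zeros((knn, knn))
    for a in range(knn):
        for b in range(knn):
            H[a, b] = float(B[a] @ B[b])
        H[a, a] += lam * d[a] ** 2
    kkt = np.zeros((knn + 1, knn + 1))
    kkt[:knn, :knn] = 2 * H
    kkt[:knn, knn] = 1
    kkt[knn, :knn] = 1
    rhs = np.zeros(knn + 1)
    rhs[:knn] = 2 * (B @ x)
    rhs[knn] = 1
    sol = np.linalg.solve(kkt, rhs)
    coeff = np.zeros(k)
    for i, j in enumerate(support):
        coeff[j] = sol[i]
    return coeff


# ---- LSTM gate equations --------------------------------------------------

def sigmoid_bf(z):
    return 1.0 / (1.0 + math.exp(-z))


def lstm_step_bf(x, h_prev, c_prev, W, b, forget_bias):
    """Straight-line, loop-free-in-spirit evaluation of one LSTM step.

    Gate blocks in W/b ordered [f, i, g, o]; W rows are [h_prev | x].
    Scalar arithmetic throughout, one unit at a time.
    """
    H = len(h_prev)
    inp = list(h_prev) + list(x)
    z = [sum(inp[r] * W[r][c] for r in range(len(inp))) + b[c]
         for c in range(4 * H)]
    f = [sigmoid_bf(z[j] + forget_bias) for j in range(H)]
    i = [sigmoid_bf(z[H + j]) for j in range(H)]
    g = [math.tanh(z[2 * H + j]) for j in range(H)]
    o = [sigmoid_bf(z[3 * H + j]) for j in range(H)]
    c_new = [f[j] * c_prev[j] + i[j] * g[j] for j in range(H)]
    h_new = [o[j] * math.tanh(c_new[j]) for j in range(H)]
    return h_new, c_new
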