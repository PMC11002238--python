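"""Independent, loop-based reimplementations of every window index.

These deliberately avoid the vectorized/pandas code paths of the package:
all data reductions are explicit Python loops; only eigen-decompositions
fall back to numpy/scipy routines (and a *different* routine than the
package uses where possible).  They serve as oracles in the equivalence
tests.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg


def _isnan(v) -> bool:
    return v != v


def naive_pairwise_cov(x):
    """Pairwise-complete covariance (ddof=1) and counts, by loops."""
    n, p = len(x), len(x[0])
    cov = [[float("nan")] * p for _ in range(p)]
    counts = [[0] * p for _ in range(p)]
    for i in range(p):
        for j in range(p):
            pairs = [
                (x[t][i], x[t][j])
                for t in range(n)
                if not _isnan(x[t][i]) and not _isnan(x[t][j])
            ]
            counts[i][j] = len(pairs)
            if len(pairs) < 2:
                continue
            mi = sum(a for a, _ in pairs) / len(pairs)
            mj = sum(b for _, b in pairs) / len(pairs)
            cov[i][j] = sum((a - mi) * (b - mj) for a, b in pairs) / (len(pairs) - 1)
    return cov, counts


def naive_variance_indices(x):
    n, p = len(x), len(x[0])
    cov, _ = naive_pairwise_cov(x)
    diags = [cov[i][i] for i in range(p) if not _isnan(cov[i][i])]
    out = {
        "Av_Var": sum(diags) / len(diags) if diags else float("nan"),
        "NMV": max(diags) if diags else float("nan"),
    }
    offs = [abs(cov[i][j]) for i in range(p) for j in range(p) if i != j and not _isnan(cov[i][j])]
    out["Max_cov"] = max(offs) if offs else float("nan")
    sub, cols = naive_complete_submatrix(x)
    if len(sub) >= 3 and len(cols) >= 2:
        c, _ = naive_pairwise_cov(sub)
        lam = np.linalg.eigvalsh(np.array(c))
        tr = sum(c[i][i] for i in range(len(cols)))
        out["PC_var"] = float(lam[-1])
        out["Ex_var"] = float(lam[-1]) / tr if tr > 0 else float("nan")
    else:
        out["PC_var"] = float("nan")
        out["Ex_var"] = float("nan")
    return out


def naive_complete_submatrix(x):
    """Rows complete across columns having >= 2 observations."""
    n, p = len(x), len(x[0])
    cols = [j for j in range(p) if sum(0 if _isnan(x[t][j]) else 1 for t in range(n)) >= 2]
    sub = []
    for t in range(n):
        row = [x[t][j] for j in cols]
        if all(not _isnan(v) for v in row):
            sub.append(row)
    return sub, cols


def naive_lag1_ac(series):
    s = [v for v in series if not _isnan(v)]
    if len(s) < 3:
        return float("nan")
    a, b = s[:-1], s[1:]
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    sa = math.sqrt(sum((v - ma) ** 2 for v in a) / len(a))
    sb = math.sqrt(sum((v - mb) ** 2 for v in b) / len(b))
    if sa == 0 or sb == 0:
        return float("nan")
    return sum((u - ma) * (v - mb) for u, v in zip(a, b)) / len(a) / (sa * sb)


def naive_ac_indices(x):
    n, p = len(x), len(x[0])
    acs = [naive_lag1_ac([x[t][j] for t in range(n)]) for j in range(p)]
    acs = [a for a in acs if not _isnan(a)]
    if not acs:
        return {"Av_Ac": float("nan"), "Max_ac": float("nan")}
    return {"Av_Ac": sum(acs) / len(acs), "Max_ac": max(acs)}


def naive_maf(x, min_obs=13):
    n, p = len(x), len(x[0])
    rows = [list(x[t]) for t in range(n) if all(not _isnan(v) for v in x[t])]
    nan = {"MAF_ac": float("nan"), "MAF_var": float("nan"), "MAF_ev": float("nan")}
    if len(rows) < min_obs or p < 2:
        return nan
    sigma, _ = naive_pairwise_cov(rows)
    diffs = [[rows[t + 1][j] - rows[t][j] for j in range(p)] for t in range(len(rows) - 1)]
    sigma_d, _ = naive_pairwise_cov(diffs)
    sigma = np.array(sigma)
    sigma_d = np.array(sigma_d)
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] <= 1e-12 * max(eig[-1], 1e-300):
        sigma = sigma + (1e-8 * np.trace(sigma) / p) * np.eye(p)
    lam, vec = scipy.linalg.eig(sigma_d, sigma)  # general routine, unlike the package
    order = np.argsort(lam.real)
    lam1 = max(float(lam.real[order[0]]), 0.0)
    v = vec[:, order[0]].real
    v = v / math.sqrt(sum(vi**2 for vi in v))
    means = [sum(r[j] for r in rows) / len(rows) for j in range(p)]
    scores = [sum((r[j] - means[j]) * v[j] for j in range(p)) for r in rows]
    ms = sum(scores) / len(scores)
    var = sum((s - ms) ** 2 for s in scores) / (len(scores) - 1)
    return {"MAF_ac": naive_lag1_ac(scores), "MAF_var": var, "MAF_ev": lam1}


def naive_df(x):
    sub, cols = naive_complete_submatrix(x)
    if len(sub) < 4 or len(cols) < 1:
        return float("nan")
    c, _ = naive_pairwise_cov(sub)
    c = np.atleast_2d(np.array(c))
    if not any(c[i][i] > 0 for i in range(len(cols))):
        return float("nan")
    lam, vec = np.linalg.eigh(c)
    u = vec[:, -1]
    means = [sum(r[j] for r in sub) / len(sub) for j in range(len(cols))]
    scores = [sum((r[j] - means[j]) * u[j] for j in range(len(cols))) for r in sub]
    return naive_lag1_ac(scores)


def naive_crosscorr(x, cap=1.0 - 1e-12):
    n, p = len(x), len(x[0])
    rs = []
    for i in range(p):
        for j in range(i + 1, p):
            pairs = [
                (x[t][i], x[t][j])
                for t in range(n)
                if not _isnan(x[t][i]) and not _isnan(x[t][j])
            ]
            if len(pairs) < 3:
                continue
            mi = sum(a for a, _ in pairs) / len(pairs)
            mj = sum(b for _, b in pairs) / len(pairs)
            si = math.sqrt(sum((a - mi) ** 2 for a, _ in pairs) / len(pairs))
            sj = math.sqrt(sum((b - mj) ** 2 for _, b in pairs) / len(pairs))
            if si == 0 or sj == 0:
                continue
            r = sum((a - mi) * (b - mj) for a, b in pairs) / len(pairs) / (si * sj)
            rs.append(r)
    if not rs:
        return {"Av_ab_cc": float("nan"), "MI": float("nan")}
    mis = [-0.5 * math.log(1.0 - min(r * r, cap)) for r in rs]
    return {"Av_ab_cc": sum(abs(r) for r in rs) / len(rs), "MI": sum(mis) / len(mis)}


def naive_mmd(times, x, ref_cov):
    """Per-visit statistical distance by explicit loops."""
    out = []
    for t in range(1, len(x)):
        shared = [
            j for j in range(len(x[t])) if not _isnan(x[t][j]) and not _isnan(x[t - 1][j])
        ]
        if not shared:
            continue
        delta = np.array([x[t][j] - x[t - 1][j] for j in shared])
        s = np.array([[ref_cov[i][j] for j in shared] for i in shared])
        try:
            sol = np.linalg.solve(s, delta)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(s) @ delta
        out.append((times[t], math.sqrt(max(float(delta @ sol), 0.0))))
    return out


def naive_window_cvs(x, min_obs=3):
    n, p = len(x), len(x[0])
    cvs = []
    for j in range(p):
        col = [x[t][j] for t in range(n) if not _isnan(x[t][j])]
        if len(col) < min_obs:
            cvs.append(float("nan"))
            continue
        m = sum(col) / len(col)
        sd = math.sqrt(sum((v - m) ** 2 for v in col) / (len(col) - 1))
        cvs.append(sd / m if m > 0 else float("nan"))
    return cvs


def naive_auc(outcome, predictor):
    """Pairwise concordance (ties counted half)."""
    pos = [p for o, p in zip(outcome, predictor) if o]
    neg = [p for o, p in zip(outcome, predictor) if not o]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_pearson(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    sa = math.sqrt(sum((v - ma) ** 2 for v in a) / n)
    sb = math.sqrt(sum((v - mb) ** 2 for v in b) / n)
    return sum((u - ma) * (v - mb) for u, v in zip(a, b)) / n / (sa * sb)
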