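"""Two-library differential expression for tag counts.

Significance uses the Audic-Claverie conditional test: given ``x`` counts of
a tag in library A (total ``N_A``), the count ``y`` in library B (total
``N_B``) follows, under the null of equal underlying frequency,

    p(y | x) = (N_B/N_A)^y (x+y)! / (x! y! (1 + N_B/N_A)^(x+y+1))

which is the negative binomial NB(r = x+1, p = N_A/(N_A+N_B)).  The
two-sided p-value is ``min(1, 2 * min(lower tail, upper tail))`` with both
tails including the observed count; tails are evaluated in log space.

Fold change follows the SAGE convention: the ratio R of normalised
frequencies (tpm) with zero frequencies replaced by one, reported directly
when R >= 1 and as -1/R otherwise, so |FC| >= 1 and negative values denote
repression.  A tag is up-regulated (UR) when p <= alpha and FC > 1,
down-regulated (DR) when p <= alpha and FC < -1, and not significant (ns)
otherwise; no multiple-testing correction is applied by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from supersage.tags import UnitagTable

CONTRAST_COLUMNS = [
    "tag",
    "count_A",
    "count_B",
    "tpm_A",
    "tpm_B",
    "p_value",
    "fold_change",
    "regulation",
]


def ac_pvalue(x, total_a, y, total_b):
    """Two-sided Audic-Claverie p-value for tag counts x (of total_a) vs y
    (of total_b).  Accepts scalars or arrays; returns matching shape."""
    x = np.asarray(x)
    y = np.asarray(y)
    scalar = x.ndim == 0 and y.ndim == 0
    x = np.atleast_1d(x).astype(np.int64)
    y = np.atleast_1d(y).astype(np.int64)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("tag counts must be non-negative")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    q = total_a / (total_a + total_b)
    log_lower = stats.nbinom.logcdf(y, x + 1, q)
    log_upper = stats.nbinom.logsf(y - 1, x + 1, q)
    p = np.minimum(1.0, 2.0 * np.exp(np.minimum(log_lower, log_upper)))
    # both tails include the observed count, so p >= pmf(y) > 0
    return float(p[0]) if scalar else p


def fold_change(f_a, f_b):
    """Signed fold change of normalised frequencies A over B.

    Zero frequencies are replaced by one before the ratio R = f_A/f_B; the
    result is R when R >= 1 and -1/R otherwise, so |FC| >= 1 always and
    FC(f, f) = 1.  Accepts scalars or arrays.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    scalar = f_a.ndim == 0 and f_b.ndim == 0
    a = np.where(np.atleast_1d(f_a) == 0, 1.0, np.atleast_1d(f_a))
    b = np.where(np.atleast_1d(f_b) == 0, 1.0, np.atleast_1d(f_b))
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("frequencies must be non-negative")
    ratio = a / b
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return float(fc[0]) if scalar else fc


def classify(p_value, fc, alpha: float = 0.05):
    """UR / DR / ns classification at significance level alpha.

    UR: p <= alpha and FC > 1; DR: p <= alpha and FC < -1; everything else
    (including |FC| = 1, which has no direction) is ns.
    """
    p_value = np.asarray(p_value, dtype=float)
    fc = np.asarray(fc, dtype=float)
    scalar = p_value.ndim == 0 and fc.ndim == 0
    p_value = np.atleast_1d(p_value)
    fc = np.atleast_1d(fc)
    out = np.full(np.broadcast(p_value, fc).shape, "ns", dtype=object)
    significant = p_value <= alpha
    out[significant & (fc > 1)] = "UR"
    out[significant & (fc < -1)] = "DR"
    return str(out[0]) if scalar else out


def adjust_pvalues(p, method: str):
    """Multiple-testing adjustment: 'bonferroni' or 'bh' (Benjamini-Hochberg)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p
    if method == "bonferroni":
        return np.minimum(1.0, p * n)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise ValueError(f"unknown correction method {method!r}")


def run_contrast(
    table_a: UnitagTable,
    table_b: UnitagTable,
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Test every unitag of a two-library contrast (A relative to B).

    Both tables must be singlet-filtered and tpm-normalised.  The unitag set
    is the union of the two retained sets; a tag absent from one library
    enters with count 0 (and frequency 0, handled by the zero->1 rule of
    :func:`fold_change`).  Classification uses raw p-values by default; pass
    ``correction='bonferroni'`` or ``'bh'`` to classify on adjusted ones.
    Returns the per-tag table and a summary with UR + DR + ns = unitags.
    """
    for table in (table_a, table_b):
        if not table.filtered:
            raise ValueError(
                f"library {table.library!r} is not singlet-filtered; "
                "run exclude_singlets first"
            )
        if table.tpm is None:
            raise ValueError(
                f"library {table.library!r} is not normalised; run normalize_tpm first"
            )
    total_a, total_b = table_a.total, table_b.total
    tags = sorted(set(table_a.counts) | set(table_b.counts))
    x = np.array([table_a.counts.get(t, 0) for t in tags], dtype=np.int64)
    y = np.array([table_b.counts.get(t, 0) for t in tags], dtype=np.int64)
    tpm_a = np.array([table_a.tpm.get(t, 0.0) for t in tags])
    tpm_b = np.array([table_b.tpm.get(t, 0.0) for t in tags])
    if tags:
        p = ac_pvalue(x, total_a, y, total_b)
        fc = fold_change(tpm_a, tpm_b)
        p_class = adjust_pvalues(p, correction) if correction else p
        regulation = classify(p_class, fc, alpha)
    else:
        p = np.array([])
        fc = np.array([])
        regulation = np.array([], dtype=object)
    result = pd.DataFrame(
        {
            "tag": tags,
            "count_A": x,
            "count_B": y,
            "tpm_A": tpm_a,
            "tpm_B": tpm_b,
            "p_value": p,
            "fold_change": fc,
            "regulation": regulation,
        }
    )
    summary = {
        "contrast": f"{table_a.library}_vs_{table_b.library}",
        "UR": int((result["regulation"] == "UR").sum()),
        "DR": int((result["regulation"] == "DR").sum()),
        "ns": int((result["regulation"] == "ns").sum()),
        "unitags": len(result),
    }
    return result, summary


def summary_table(summaries: list[dict]) -> pd.DataFrame:
    """Stack contrast summaries into a rows-by-contrast table
    (rows UR / DR / ns / Unitags, one column per contrast plus a total)."""
    columns = {s["contrast"]: [s["UR"], s["DR"], s["ns"], s["unitags"]] for s in summaries}
    frame = pd.DataFrame(columns, index=["UR", "DR", "ns", "Unitags"])
    frame["Total"] = frame.sum(axis=1)
    return frame
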