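"""Convergent recombination vs convergent selection.

For every within-patient pair of samples, clones are split into SHARED
(present in both amino-acid junction sets) and NON_SHARED, and each group's
clone frequencies are rank-correlated with generation probability. A positive
frequency–p_gen correlation is the signature of convergent recombination
(high-probability junctions are produced, and therefore observed expanded,
many times independently); its absence among shared, hyper-expanded clones is
the signature of antigen-driven convergent selection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Repertoire
from .stats import benjamini_hochberg, spearman_ci, spearman_correlation
from .vdj import RecombinationModel, pgen_aa_many

logger = logging.getLogger(__name__)

SHARED = "SHARED"
NON_SHARED = "NON_SHARED"


@dataclass(frozen=True)
class CorrelationResult:
    group: str
    n_clones: int
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    slope: float
    intercept: float
    n_excluded_pgen_zero: int = 0
    flag: str | None = None  # "UNDEFINED" when the group is too small/degenerate


def correlate_freq_pgen(table: pd.DataFrame, scale: str = "LOG10") -> dict[str, CorrelationResult]:
    """Per sharing group: Spearman rho/p plus a least-squares line for plotting.

    ``table`` needs columns junction_aa, frequency, pgen, group (SHARED /
    NON_SHARED). Rows with pgen = 0 are excluded (and counted); rho is
    computed on the raw values (rank-based, hence scale-invariant) while the
    regression line is fit on the configured scale (default log10-log10,
    frequency on x, p_gen on y).
    """
    if scale not in ("LOG10", "LINEAR"):
        raise ValidationError("scale must be LOG10 or LINEAR")
    out: dict[str, CorrelationResult] = {}
    for group in (SHARED, NON_SHARED):
        sub = table[table["group"] == group]
        n_zero = int((sub["pgen"] <= 0).sum())
        if n_zero:
            logger.info("correlate_freq_pgen: %s: excluded %d clones with pgen=0", group, n_zero)
        sub = sub[sub["pgen"] > 0]
        n = len(sub)
        if n < 3:
            out[group] = CorrelationResult(group, n, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, n_zero, "UNDEFINED")
            continue
        res = spearman_correlation(sub["frequency"].to_numpy(), sub["pgen"].to_numpy())
        if res.flag == "CONSTANT":
            out[group] = CorrelationResult(group, n, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, n_zero, "UNDEFINED")
            continue
        x = sub["frequency"].to_numpy()
        y = sub["pgen"].to_numpy()
        if scale == "LOG10":
            x, y = np.log10(x), np.log10(y)
        slope, intercept = np.polyfit(x, y, 1)
        lo, hi = spearman_ci(res.statistic, n)
        out[group] = CorrelationResult(
            group, n, res.statistic, res.p_value, lo, hi, float(slope), float(intercept), n_zero
        )
    return out


def shared_nonshared_table(
    rep_a: Repertoire,
    rep_b: Repertoire,
    model: RecombinationModel,
    freq_mode: str = "max",
) -> pd.DataFrame:
    """Clone table for one sample pair: frequency, p_gen and sharing group.

    Shared clones (present in both samples) take, per ``freq_mode``, the max
    (default) or mean of their two within-sample frequencies; non-shared
    clones take their frequency in the sample containing them. Non-productive
    junctions ('*'/'X') are excluded before p_gen.
    """
    if freq_mode not in ("max", "mean"):
        raise ValidationError("freq_mode must be 'max' or 'mean'")
    fa = {j: f for j, f in rep_a.junction_frequencies().items() if "*" not in j and "X" not in j}
    fb = {j: f for j, f in rep_b.junction_frequencies().items() if "*" not in j and "X" not in j}
    rows = []
    for j in sorted(set(fa) | set(fb)):
        in_a, in_b = j in fa, j in fb
        if in_a and in_b:
            freq = max(fa[j], fb[j]) if freq_mode == "max" else (fa[j] + fb[j]) / 2
            group = SHARED
        else:
            freq = fa.get(j) if in_a else fb.get(j)
            group = NON_SHARED
        rows.append((j, freq, group))
    table = pd.DataFrame(rows, columns=["junction_aa", "frequency", "group"])
    table["pgen"] = pgen_aa_many(model, table["junction_aa"])
    return table


def convergence_report(
    reps: Sequence[Repertoire],
    model: RecombinationModel,
    freq_mode: str = "max",
    scale: str = "LOG10",
) -> pd.DataFrame:
    """Frequency–p_gen correlations for every within-patient/subset sample pair.

    Returns one row per (pair, group) with raw and Benjamini-Hochberg adjusted
    p-values; degenerate groups are flagged UNDEFINED, never dropped.
    """
    groups: dict[tuple[str, str], list[Repertoire]] = {}
    for rep in reps:
        groups.setdefault((rep.patient, rep.subset), []).append(rep)
    rows = []
    for (patient, subset), members in sorted(groups.items()):
        members = sorted(members, key=lambda r: (r.compartment, r.visit))
        for rep_a, rep_b in itertools.combinations(members, 2):
            table = shared_nonshared_table(rep_a, rep_b, model, freq_mode)
            results = correlate_freq_pgen(table, scale)
            for group in (SHARED, NON_SHARED):
                r = results[group]
                rows.append(
                    {
                        "patient": patient,
                        "subset": subset,
                        "sample_a": rep_a.sample_id,
                        "sample_b": rep_b.sample_id,
                        "group": group,
                        "n": r.n_clones,
                        "n_excluded_pgen_zero": r.n_excluded_pgen_zero,
                        "rho": r.rho,
                        "p": r.p_value,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "slope": r.slope,
                        "intercept": r.intercept,
                        "flag": r.flag or "",
                    }
                )
    report = pd.DataFrame(rows)
    if not report.empty:
        report["p_adj"] = benjamini_hochberg(report["p"].to_numpy())
    return report
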