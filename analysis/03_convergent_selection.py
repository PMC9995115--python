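"""Convergent recombination vs convergent selection.

Correlates clone frequency with generation probability separately for clones
shared between the two knees and clones private to one knee. Expected on the
default cohort: non-shared clone frequencies correlate positively with p_gen
(convergent recombination), while shared clones — planted as antigen-driven —
show no correlation, i.e. their expansion is not explained by generability.
"""

from _common import cohort, config
from tcrshare.pipeline import run_spatial

if __name__ == "__main__":
    cfg = config()
    bundle = run_spatial(cohort(cfg), cfg)
    report = bundle["convergence"]
    cols = ["patient", "subset", "group", "n", "rho", "p", "p_adj"]
    print(report[cols].to_string(index=False))
    shared = report[report["group"] == "SHARED"]["rho"].abs().median()
    non = report[report["group"] == "NON_SHARED"]["rho"].median()
    print(f"\nmedian |rho| shared: {shared:.3f}   median rho non-shared: {non:.3f}")
    print(f"report -> {cfg.outdir}/spatial/convergence.tsv")
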