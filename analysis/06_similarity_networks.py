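"""CDR3 k-mer similarity networks vs generative-model random repertoires.

Builds the per-patient left/right-knee Treg similarity network (edge = ≥8
shared 3-mers), extracts the top-5 clusters, and benchmarks their purity
against 100 size-matched random repertoire pairs sampled from the V(D)J
model. Expected on the default cohort: patient clusters are large and mix
left-, right- and both-knee sequences (low purity) while random-repertoire
clusters are small and side-pure — planted antigen-driven families are
detected as significantly lower purity (Mann-Whitney p < 0.05).
"""

from _common import cohort, config
from tcrshare.pipeline import run_network

if __name__ == "__main__":
    cfg = config()
    bundle = run_network(cohort(cfg), cfg)
    print("top-5 patient clusters:")
    print(bundle["cluster_stats"].to_string(index=False))
    print("\nrandom-repertoire benchmark (Mann-Whitney, patient vs random purity):")
    print(bundle["purity_tests"].to_string(index=False))
    rnd = bundle["random_cluster_stats"]
    print(f"\nrandom cluster purity median: {rnd['purity'].median():.3f} "
          f"(n={len(rnd)} clusters from {rnd['replicate'].nunique()} replicates/patient)")
    print(f"tables + GraphML -> {cfg.outdir}/network/")
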