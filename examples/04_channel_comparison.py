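"""Compare per-individual ROH statistics between technologies.

Per individual, NROH / mean size / SROH are computed over segments longer
than 1 Mb; the array baseline (h=1) is compared with the WGS channel at
h = 1..3 by Mann-Whitney-Wilcoxon rank tests and Pearson correlation.
"""

import rohcompare as rc

config = rc.preset("default", seed=7, n_individuals=12, n_chromosomes=2,
                   chromosome_length_bp=40_000_000)
array_m, wgs_m, _ = rc.simulate(config)
array_qc, _ = rc.apply_qc(array_m)
wgs_qc, _ = rc.apply_qc(wgs_m)

array_cs = rc.call_segments(array_qc, rc.ROHParams(window_het=1), "SIM")
wgs_css = rc.call_sweep(wgs_qc, h_values=(1, 2, 3), population="SIM")

results = rc.compare_channels(array_cs, wgs_css, array_m.individuals)
print(results.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

summary = rc.summarize_individuals(array_cs, array_m.individuals)
print(f"\narray baseline: mean NROH {summary['nroh'].mean():.2f}, "
      f"mean SROH {summary['sroh_mb'].mean():.1f} Mb per individual")
# A MWW p above 0.05 means the two technologies give statistically
# indistinguishable per-individual ROH distributions at that tolerance;
# correlations near 1 mean individuals rank identically in both channels.
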