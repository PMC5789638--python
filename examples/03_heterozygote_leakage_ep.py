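"""The ep statistic: observed heterozygote leakage inside called ROHs.

Tolerating h het calls per scanning window lets segments absorb observed
hets; ep summarizes that leakage as the segment-count-weighted mean of the
per-segment het fraction over 1 Mb+ length bins, as a percentage.
"""

import rohcompare as rc

# worked single-segment value: one tolerated het among 368 homozygous SNPs
seg = rc.ROHSegment("i1", 1, 1, 2_600_000, n_snp=368, n_het_observed=1)
single = rc.ROHCallSet(segments=[seg])
print(f"1 het / 368 SNPs -> ep = {rc.ep(single):.2f} %  (= 100/368)\n")

# sweep on a simulated low-coverage WGS channel
config = rc.SimConfig(
    n_individuals=6, n_chromosomes=2, chromosome_length_bp=25_000_000,
    tract_rates=((1.0, 5.0, 2.0), (5.0, 10.0, 0.5)), seed=21,
)
_, wgs_m, _ = rc.simulate(config)
wgs_qc, _ = rc.apply_qc(wgs_m)
sweep = rc.ep_sweep(wgs_qc, h_values=(1, 2, 3, 4, 5), population="SIM")
print("WGS channel, 2.4 false hets per Mb:")
for _, row in sweep.drop_duplicates("h").iterrows():
    print(f"  h={int(row['h'])}: ep = {row['ep_overall_pct']:.3f} %")
# ep grows with the tolerance: wider windows admit more of the channel's
# false heterozygotes into called segments.
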