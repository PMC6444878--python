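canonical_hi: 180
canonical_lo: 140
chrom_len: 0
depth_per_nuc: 30
diff_window: 147
dinuc_flank: 250
dyad_jitter_sd: 10.0
fc_threshold: 1.5
fdr_threshold: 0.001
footprint_gc: 0.0
fraction_shifted: 0.8
gc_fraction: 0.42
kmer_flank: 130
kmer_k: 6
kmer_window: 10
len_mean: 147.0
len_sd: 12.0
log2_pseudocount: 1.0
min_occupancy: 2.0
min_summit_distance: 40
n_genes: 60
n_nucs_per_side: 3
ndr_offset: 100
ndr_width: 150
p_bound_shifted: 0.6
p_bound_stable: 0.25
p_de_shifted: 0.5
p_de_stable: 0.1
profile_flank: 1000
role_window: 1000
seed: 7
shift_deltas:
- 30
- 75
- 125
- 175
smoothing_bandwidth: 20.0
smoothing_kernel: gaussian
spacing: 190
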