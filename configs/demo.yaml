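# Demo pipeline run: two glioma-like tumor samples with matched normals and
# one low-coverage sample that fails the per-site depth filter.
seed: 42
panel_seed: 0
out_dir: demo_run

meth_filter:
  llr_cutoff: 2.5
  min_reads: 10

llr_model:
  mu_meth: 4.0
  mu_unmeth: 4.0
  sigma: 1.5
  miscall_rate: 0.03

variant_params:
  min_candidate_frequency: 0.15
  min_candidate_depth: 10
  ploidy: 2
  error_rate: 0.05

dmr2:
  lo: 70
  hi: 81

samples:
  - sample_id: T_idh1mut
    exon_meth: 0.45
    intron_meth: 0.25
    meth_depth: 50
    pileup_depth: 200
    variants:
      - name: idh1_r132       # the CGT -> GGT hotspot substitution
        allele_fraction: 0.5
    matched_normal: true
  - sample_id: T_idh2mut
    exon_meth: 0.08
    intron_meth: 0.6
    meth_depth: 50
    pileup_depth: 200
    variants:
      - name: idh2_r172       # the AGG -> AAG hotspot substitution
        allele_fraction: 0.5
    matched_normal: true
  - sample_id: T_lowdepth
    exon_meth: 0.4
    intron_meth: 0.4
    meth_depth: 5             # below min_reads: methylation reported unusable
    pileup_depth: 200
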