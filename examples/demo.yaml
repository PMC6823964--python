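# Reduced-scale demonstration: all six evaluation designs end to end.
seed: 7
outdir: runs/demo
panel: {n_lines: 240, n_markers: 1000, n_subpops: 3, fst: 0.15, n_chroms: 7}
trait: {n_qtl: 120, effect_sd: 0.03, n_major: 2, major_effect: 0.06, target_h2: 0.48}
design: {n_envs: 8, n_reps: 2}
sweep: {sizes: [25, 50, 75, 100, 125, 150], vp_size: 60, n_samples: 10}
cycles: {n_cycles: 5, tp_size: 219, vp_size: 20}
subpop: {tp_size: 50, vp_size: 30, n_draws: 5}
fixedfx: {tp_size: 144, n_folds: 10}
independent: {n_progeny: 100, pop_type: RIL, shared_markers: 600}
response: {n_rounds: 10, n_folds: 10, n_ms_loci: 3}
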