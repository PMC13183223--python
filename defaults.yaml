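# Study-default pipeline parameters (input paths to be filled per run).
train_expr: ""
train_labels: ""
valid_expr: ""
valid_labels: ""
disease_targets: ""
chem_targets: ""
chem_targets_b: ""
network: ""
abundance: ""

lfc_min: 0.5          # |log2FC| threshold for DEGs (strict)
p_max: 0.05           # p threshold for DEGs (strict, unadjusted by default)
use_adjusted: false

apply_context_filter: false
direct_only: true     # CTD entries restricted to direct interactions
fit_top_frac: 0.2     # top 20% of pharmacophore fit scores

n_perm: 10000         # permutation iterations for the overlap null
resample: all

score_min: 0.4        # interaction confidence threshold (strict)
top_k: 20             # hub count from composite centrality

n_folds: 5            # CV folds (LASSO lambda selection; outer and inner)
repeats: 100          # nested-CV repetitions
bootstrap_B: 1000     # bootstrap iterations
max_runs: 1000        # shadow-feature iterations cap
alpha: 0.01           # shadow-feature decision level
gbt_rounds: 100

grid_thresholds: [0.25, 0.5, 0.75, 1.0, 1.25, 1.5]
seed: 0
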