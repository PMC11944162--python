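"""Stratified cross-validation and a branch-ablation comparison.

Runs multi-label stratified 3-fold cross-validation of the full model on
planted-signal data, then retrains with the drug-protein branch removed to
show how much that characterization contributes.
"""

from adrfusion.evaluation import (run_ablation, run_crossval,
                                  stratified_multilabel_kfold)
from adrfusion.fusion import PipelineConfig, TrainConfig, build_features
from adrfusion.synthetic_data import SyntheticConfig, generate_dataset

ds = generate_dataset(SyntheticConfig(n_drugs=200, n_labels=8, n_proteins=12,
                                      pairs_per_drug_mean=4.0,
                                      signal_strength=1.0, seed=21))
pc = PipelineConfig.study_scale()
bundle = build_features(ds.drugs, ds.dp_pairs, ds.proteins, pc)
tc = TrainConfig(lr=3e-3, epochs=120, batch_size=64, seed=0,
                 weight_decay=3e-3, patience=15)

fa = stratified_multilabel_kfold(ds.adr_table.Y, k=3, seed=0)
sizes = fa.sizes()
print(f"fold sizes: {sizes.tolist()} (stratified over {ds.adr_table.Y.shape[1]} labels)")

full = run_crossval(bundle, ds.adr_table, pc, tc, fold_assignment=fa,
                    folds=[0])
no_dp = run_ablation(bundle, ds.adr_table, fa, "drop_dp", pc, tc, folds=[0])

print(f"full model    : F1 {full.macro_f1:.3f}  ROC-AUC {full.macro_roc_auc:.3f}  "
      f"AUPR {full.macro_aupr:.3f}")
print(f"without dp-GCN: F1 {no_dp.macro_f1:.3f}  ROC-AUC {no_dp.macro_roc_auc:.3f}  "
      f"AUPR {no_dp.macro_aupr:.3f}")
print("\nThe gap is the held-out value of the drug-protein interaction "
      "branch: part of the planted signal lives only in the protein "
      "partners, which no other branch can see.")
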