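"""Train the full multi-view pipeline on synthetic data and evaluate it.

Runs a desk-scale version of the two-stage protocol: per-view image VAE and
feature beta-VAE training, then a softmax head on the concatenated posterior
means, for all three modes (multi-view and the two single-view ablations).
Prints test accuracy and AUC per mode — on strong-signal synthetic data the
multi-view AUC should be near 1 and at least as high as either single view.
"""

from pathlib import Path

from vaefusion.pipeline import MODES, RunConfig, run_evaluate, run_train
from vaefusion.synthetic_data import SyntheticConfig, generate

root = Path("scratch/example_run")
manifest = generate(SyntheticConfig(n_patients=60, image_size=32,
                                    positive_fraction=0.6, seed=7), root)
config = RunConfig(manifest=str(manifest), image_root=str(root),
                   output_dir=str(root / "run"), image_size=32,
                   image_epochs=25, feature_epochs=40, classifier_epochs=200,
                   seed=1)
result = run_train(config, modes=list(MODES))
for mode, stats in result["metrics"]["modes"].items():
    print(f"{mode:>13}: accuracy={stats['accuracy']:.3f} auc={stats['auc']:.3f}")

report = run_evaluate(config)
print("\nDeLong p-values between modes (None if the test split is too small):")
for a, row in report["delong_p"].items():
    print(f"  {a:>13}: " + "  ".join(
        f"{b}={p if p is None else round(p, 3)}" for b, p in row.items()))
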