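"""Train the perturbation-enhanced mean teacher on scarce labels.

Generates a small synthetic dataset (10% labeled), trains the supervised
baseline and the full method for a few hundred iterations, and prints the
validation Dice of each.  The semi-supervised run uses the unlabeled pool
through the uncertainty-masked consistency loss; the supervised baseline
sees only the labeled images.
"""

from dataclasses import replace

from pemt import DatasetSpec, TrainConfig, fit, generate_dataset

spec = DatasetSpec(n_total=100, labeled_fraction=0.05, image_size=32,
                   boundary_blur_sigma=0.75, n_val=10, seed=3)
dataset = generate_dataset(spec)
print(f"dataset: {len(dataset.labeled)} labeled / {len(dataset.unlabeled)} "
      f"unlabeled / {len(dataset.validation)} validation images")

base = TrainConfig(variant="supervised", t_max=400, batch_labeled=4,
                   batch_unlabeled=4, seed=3)
for variant in ("supervised", "pemt"):
    result = fit(dataset, replace(base, variant=variant))
    m = result.val_metrics
    print(f"{variant:>10}: DSC={m['dsc']:.4f}  JAC={m['jac']:.4f}  "
          f"HD95={m['hd95']:.2f}px  ASD={m['asd']:.2f}px")

print("\nHigher DSC/JAC and lower HD95/ASD are better; the pemt run uses the")
print("95% of images that have no labels, which the baseline cannot touch.")
print("At this desk scale the margin is modest (fractions of a Dice point)")
print("and varies with the sampled dataset; the acceptance script runs the")
print("full variant comparison.")
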