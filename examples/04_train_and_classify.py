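"""Train the 21-8-5 network and classify held-out organisms.

Runs a reduced version of the full benchmark: 10 training and 6 test
micrographs per genus, extract -> train (momentum backpropagation,
cross-validated early stopping) -> evaluate, and prints the confusion
matrix.  The full-size benchmark (40 train / 50 test per genus) is what
scripts/acceptance.py reproduces.
"""

import dataclasses

from algascope import PipelineConfig, run_benchmark

config = dataclasses.replace(PipelineConfig(), n_train_per_class=10,
                             n_test_per_class=6)
report = run_benchmark(seed=3, config=config)

print(report.confusion_frame())
print(f"\noverall accuracy: {100 * report.overall_accuracy:.1f}% "
      f"on {len(report.predictions)} test images")
print(f"training epochs: {len(report.train_rmse)}, "
      f"final validation RMSE: {report.val_rmse[-1]:.4f}")
# rows are the true genera, columns the predictions; the trailing
# Unidentified column collects rejections (winning activation below the
# confidence threshold), which is how foreign objects are handled.
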