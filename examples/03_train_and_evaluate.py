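"""Train the 21-3-3 ANN on a synthetic subject and score it offline.

For a quick demonstration this uses a compressed protocol (2 s holds, 2
sessions) and a short schedule; the full study conditions (10 sessions of
115 s, lr 1e-4, batch 5, 6000 epochs) are exercised by the test suite and
acceptance script and reach ~99% offline accuracy.
"""

from dataclasses import replace

import emgsleeve as es

protocol = replace(es.SessionProtocol(), calibration_s=5.0, hold_s=2.0,
                   rest_s=3.0, n_datasets=4, train_fraction=2)
cfg = es.PipelineConfig(
    protocol=protocol,
    ann_hyperparams=replace(es.TrainConfig(), epochs=600, learning_rate=5e-3),
    seed=7,
)

result = es.run_subject_study(cfg)
cm = result.offline_cm

print(f"trained {'-'.join(map(str, result.model.layer_sizes))} network, "
      f"final epoch MSE {result.loss_history[-1]:.4f}")
print(f"offline accuracy on held-out sessions: {100 * cm.accuracy():.1f}% "
      f"({cm.total} bins)")
print("per-class diagonal (row-normalized %):")
for g in cm.classes:
    print(f"  {g.name:<16} {100 * cm.class_accuracy(g):5.1f}%")
print("the confusion matrix rows are true poses, columns predictions; "
      "off-diagonal mass marks poses the 3-bit code confuses")
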