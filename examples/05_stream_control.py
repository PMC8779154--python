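"""Stream a held-out session through the online control loop.

One gesture decision is issued per 270 ms bin, decoded from the network's
3-bit state vector and mapped to servo flexion flags; per-hold verdicts use
the modal non-rest decision inside each pose window.
"""

from dataclasses import replace

import emgsleeve as es
from emgsleeve.control import (gesture_to_command, hold_bin_windows,
                               score_online_trials, stream_classify)

protocol = replace(es.SessionProtocol(), calibration_s=5.0, hold_s=2.0,
                   rest_s=3.0, n_datasets=4, train_fraction=2)
cfg = es.PipelineConfig(
    protocol=protocol,
    ann_hyperparams=replace(es.TrainConfig(), epochs=600, learning_rate=5e-3),
    seed=7,
)
result = es.run_subject_study(cfg)

session = result.test_sessions[0]
timeline = stream_classify(result.model, session, cfg)
print(f"{len(timeline.decisions)} decisions at {timeline.step_s * 1000:.0f} ms "
      f"intervals over a {session.duration_s:.0f} s session")

# what the hand would do for the first decision inside the first hold
windows = hold_bin_windows(cfg.protocol, cfg.fs, cfg.bin_config)
start, end, pose = windows[0]
g = timeline.decisions[start + 1]
cmd = gesture_to_command(g)
flexed = [f for f in ("thumb", "index", "middle", "ring", "pinky")
          if getattr(cmd, f)]
print(f"first decision inside the {pose.name} hold: {g.name} "
      f"-> servos flexed: {flexed or 'none'}")

cm = score_online_trials(timeline, windows)
print(f"online trial verdicts correct: {cm.accuracy():.0%} of "
      f"{cm.total} holds — each hold scored by its modal non-rest decision")
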