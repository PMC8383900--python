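"""Train the compact segmentation network on synthetic fundus images.

Renders a small training set, fits the tiny encoder-decoder for a few
epochs, and scores the held-out prediction against the rendered truth.
(A larger run - 240 images, 10 epochs at 128 px - is what the acceptance
script uses; this demo keeps the sizes small so it finishes in seconds.)
"""

import fundtess as ft

n_train, n_eval = 30, 5
scenes = [ft.generate_image(ft.SynthImageParams(
    size=64, rho_target=0.10 + 0.2 * (i % 5) / 4, seed=1000 + i))
    for i in range(n_train + n_eval)]
pairs = [(s.image, s.choroid_truth) for s in scenes]

spec = ft.SegModelSpec(encoder_depth="tiny", input_size=64, epochs=8,
                       batch_size=4, seed=0)
model = ft.train(pairs[:n_train], spec)
print(f"training loss: {model.history[0]:.4f} -> {model.history[-1]:.4f}")

tp = tn = fp = fn = 0
for scene in scenes[n_train:]:
    conf = model.predict_confidence(scene.image)
    pred = ft.threshold_confidence(conf, 0.5)
    c = ft.confusion(pred, scene.choroid_truth, scene.roi_truth)
    tp, tn, fp, fn = tp + c.tp, tn + c.tn, fp + c.fp, fn + c.fn

acc, sens, spec_ = ft.metrics(ft.ConfusionCounts(tp, tn, fp, fn))
print(f"held-out pixel accuracy {acc:.3f}, sensitivity {sens:.3f}, "
      f"specificity {spec_:.3f}")
# accuracy: fraction of ROI pixels classified correctly; sensitivity:
# fraction of true exposed-choroid pixels recovered by the model.
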