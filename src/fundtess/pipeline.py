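"""End-to-end FTD pipeline over a directory of fundus photographs.

For each readable image: preprocess (denoise, ROI, normalize, enhance),
extract exposed choroid with either the trained segmentation model or the
channel-subtraction labeler, and compute FTD. Unreadable images or
images with no detectable fundus field are recorded as skipped rows, and
the run continues — mirroring field studies where unassessable
photographs are excluded rather than aborting the batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .autolabel import AutolabelConfig, auto_label
from .density import compute_ftd
from .errors import FundtessError, NoInput
from .image import FundusImage
from .preprocess import PreprocessConfig, preprocess
from .segmentation import SegModel, threshold_confidence

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    autolabel: AutolabelConfig = field(default_factory=AutolabelConfig)
    confidence_threshold: float = 0.5
    save_masks: bool = True


def run_pipeline(images_dir: str | Path, out_dir: str | Path,
                 model: SegModel | None = None,
                 cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Process every image in ``images_dir``; write ``ftd.csv`` and masks.

    ``model=None`` selects the no-training channel-subtraction backend.
    Returns the result table: one row per image with ``rho``, ``s1_px``,
    ``s_px``, and ``status`` (``ok`` or a failure reason for skipped
    images).
    """
    cfg = cfg or PipelineConfig()
    images_dir = Path(images_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in images_dir.iterdir()
                   if p.suffix.lower() in _IMAGE_SUFFIXES
                   and not p.stem.startswith(("mask_", "roi_")))
    if not paths:
        raise NoInput(f"no readable images in {images_dir}")

    rows = []
    for path in paths:
        row = {"image": path.name, "rho": None, "s1_px": None, "s_px": None,
               "status": "ok"}
        try:
            img = FundusImage.open(path)
            pre = preprocess(img, cfg.preprocess)
            if model is not None:
                cmap = model.predict_confidence(pre.enhanced)
                choroid = threshold_confidence(cmap, cfg.confidence_threshold)
            else:
                choroid = auto_label(pre.enhanced, pre.roi, cfg.autolabel)
            result = compute_ftd(choroid, pre.roi)
            row.update(rho=result.rho, s1_px=result.s1_px, s_px=result.s_px)
            if cfg.save_masks:
                pre.roi.save(out / f"{path.stem}_roi.png")
                choroid.clipped_to(pre.roi).save(out / f"{path.stem}_choroid.png")
        except (FundtessError, OSError) as exc:
            row["status"] = f"skipped: {type(exc).__name__}: {exc}"
        rows.append(row)

    table = pd.DataFrame(rows)
    table.to_csv(out / "ftd.csv", index=False)
    log = {
        "backend": "model" if model is not None else "autolabel",
        "n_images": len(paths),
        "n_ok": int((table["status"] == "ok").sum()),
        "preprocess": vars(cfg.preprocess),
        "autolabel": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in vars(cfg.autolabel).items()},
        "confidence_threshold": cfg.confidence_threshold,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return table
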