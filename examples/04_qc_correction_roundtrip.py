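"""Export labels for manual correction, edit, re-import, recompute metrics.

Flagged cases are exported as a NIfTI label map (+ JSON code-map sidecar),
corrected in any external editor, and read back; metrics are recomputed
inside the corrected ROI.
"""

import tempfile
from pathlib import Path

import numpy as np

from imfseg import (
    LABEL_CODES,
    LabelVolume,
    PipelineConfig,
    calf_1T,
    generate_phantom,
    recompute_from_labels,
    segment_case,
)
from imfseg.qc import export_tags, import_tags

result = generate_phantom(calf_1T(true_imf_fraction=8.0, seed=42))
config = PipelineConfig(slice_preset="calf_1T")
case = segment_case(result.volume, config)
print(f"before correction: IMF% {case.metrics.IMF_pct:.2f}, status {case.qc.status}")

with tempfile.TemporaryDirectory() as tmp:
    tag_path = Path(tmp) / "case_tags.nii.gz"
    export_tags(case.labels, case.volume, tag_path)

    # simulate an external edit: strip the anterior third of the ROI
    edited = import_tags(tag_path, case.volume).labels.copy()
    band = edited[:, :140, :]
    band[band == LABEL_CODES["muscle"]] = 0
    band[band == LABEL_CODES["fat_round1"]] = 0
    band[band == LABEL_CODES["fat_round2_partial"]] = 0
    corrected = LabelVolume(labels=edited)

    redone = recompute_from_labels(corrected, case.volume, config, rerun_itsa=True)
    print(f"after correction:  IMF% {redone.metrics.IMF_pct:.2f}, status {redone.qc.status}")
# Removing ROI voxels can only shrink the fat volume; thresholds are
# re-derived inside the corrected ROI (rerun_itsa=True).
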