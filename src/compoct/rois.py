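"""Region-of-interest naming shared across the package.

Twelve ROIs are segmented on an L3 slice: ten skeletal muscle groups and
the two adipose depots.  The muscle groups carry synthetic names
``m01..m10`` (eight abdominal-wall / paraspinal sectors plus the two
psoas bellies); their union is the pooled muscle ROI used for all
muscle-level indices.
"""

MUSCLE_ROIS: tuple[str, ...] = tuple(f"m{i:02d}" for i in range(1, 11))
FAT_ROIS: tuple[str, ...] = ("VAT", "SAT")
ROI_NAMES: tuple[str, ...] = MUSCLE_ROIS + FAT_ROIS

# integer codes of the phantom label map
LABEL_BACKGROUND = 0
LABEL_MUSCLE = {name: i + 1 for i, name in enumerate(MUSCLE_ROIS)}  # 1..10
LABEL_VAT = 11
LABEL_SAT = 12
LABEL_BONE = 13
LABEL_GAS = 14
LABEL_OTHER_SOFT = 15

LABEL_CODES = {
    "background": LABEL_BACKGROUND,
    **{name: code for name, code in LABEL_MUSCLE.items()},
    "VAT": LABEL_VAT,
    "SAT": LABEL_SAT,
    "bone": LABEL_BONE,
    "gas": LABEL_GAS,
    "other_soft_tissue": LABEL_OTHER_SOFT,
}
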