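# CMS CT quality-measure noise thresholds (HU) for the exam categories
# bundled with this package.  The full measure defines 18 categories; only
# these seven ship here — extend or override with a user file of the same
# layout.
renal_stone:
  body_region: Abdomen
  dose_category: Low
  noise_threshold_hu: 64
abd_pelvis_wo:
  body_region: Abdomen
  dose_category: Routine
  noise_threshold_hu: 29
enterography:
  body_region: Abdomen
  dose_category: Routine
  noise_threshold_hu: 29
urogram:
  body_region: Abdomen
  dose_category: High
  noise_threshold_hu: 29
renal_mass_wo:
  body_region: Abdomen
  dose_category: High
  noise_threshold_hu: 29
chest_wo:
  body_region: Chest
  dose_category: Routine
  noise_threshold_hu: 49
pe:
  body_region: Chest
  dose_category: High
  noise_threshold_hu: 49
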