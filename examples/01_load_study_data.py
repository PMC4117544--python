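"""Load the bundled pond-study data and look at its structure.

The dataset is a stratified mesocosm experiment: four earthen ponds stocked
at 0 (control), 0.32, 1.75 and 5.24 fish/m3, each sampled with 27 one-litre
water grabs (9 transects x 3 water-column positions) on days 1, 5 and 10.
Each record is one sample scored 0/1 for a positive eDNA qPCR assay.
"""

import ednadetect as ed

study = ed.builtin_pond_study()
print(study)  # 324 samples, 28 detections

control = ed.subset(study, pond_id=1)
stocked = ed.subset(study, predicate=lambda d: d["pond_id"] != 1)
print(f"control pond:  {len(control)} samples, {control.n_detections} detections")
print(f"stocked ponds: {len(stocked)} samples, {stocked.n_detections} detections")

# detections by pond-day-position cell for the high-density pond's last day:
cell = study.df.query("pond_id == 4 and day == 10")
print(cell.groupby("position", sort=False)["detection"].sum().to_string())
# Surface and bottom carry most detections; the stocked-pond detection rate
# is 28/243 (about 12%) overall.
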