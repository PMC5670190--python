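"""Bundled worked example: an inter-laboratory droplet-generator comparison.

Published summary numbers from a two-generator (DG8 manual vs DG32
automated) ddPCR study of a certified GM-soybean reference material
(A2704-12 event, Le1 endogene, duplex assay, 100x dilution, 18 replicates
per generator).  Concentrations are the reported group means at the
manufacturer's fixed droplet volume of 0.85 nL; the measured droplet
volumes come from the optical-microscopy volume study.

These constants are *inputs* for worked examples and cross-checks — every
derived quantity (rescaled concentrations, biases, GM%) is recomputed by
the package at run time.
"""

FIXED_VD_NL = 0.85
MEASURED_VD_NL = {"DG8": 0.715, "DG32": 0.739}

#: group-mean concentrations (copies/uL) at the fixed 0.85 nL volume
MEAN_CONCENTRATION = {
    ("DG8", "A2704-12"): 115_351.0,
    ("DG8", "Le1"): 119_230.0,
    ("DG32", "A2704-12"): 114_131.0,
    ("DG32", "Le1"): 117_369.0,
}

#: reported repeatability RSDs (%) per generator and target
RSDR_PERCENT = {
    ("DG8", "A2704-12"): 5.73,
    ("DG8", "Le1"): 5.37,
    ("DG32", "A2704-12"): 5.69,
    ("DG32", "Le1"): 5.39,
}

#: per-day mean droplet volumes (nL) for the DG8 generator at one laboratory
DG8_DAY_MEAN_VOLUME_NL = [0.716, 0.702, 0.723]

REPLICATES_PER_GENERATOR = 18
DILUTION = 100.0
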