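"""Bundled worked-example index table.

Per-organ avoidance/preference indices for miRNAs of the two oldest age
classes, as produced by a genome-wide run of this kind of pipeline on
public human organ atlases (10 organs, context-score predicted sites at
the middle stringency). ``None`` marks organs where the index was "not in
order" or not available. These values feed the worked example in the
README and exercise the paired signed-rank comparison at desk scale.
"""

from __future__ import annotations

ORGANS = (
    "brain", "heart", "kidney", "liver", "ovary",
    "pancreas", "prostate", "thyroid", "placenta", "testis",
)

#: Avoidance index A per organ, oldest (ante-eutherian) age class.
AVOIDANCE_ANTE = (35.0, 11.0, 7.7, 9.1, 7.0, 4.0, 4.0, 3.6, 6.2, None)
#: Avoidance index A per organ, second-oldest (eutherian) age class.
AVOIDANCE_EUTH = (None, 2.5, None, 4.6, None, 0.8, 0.8, 0.3, None, None)

#: Preference index H per organ for the same two age classes.
PREFERENCE_ANTE = (None, 12.0, 1.6, 5.7, 2.1, 5.0, 2.6, 2.1, 4.1, None)
PREFERENCE_EUTH = (1.0, 5.2, None, 3.9, None, 1.8, 1.9, 0.7, None, None)

#: Λ-shape calls per organ ("lambda" or None).
SHAPE_ANTE = (
    None, "lambda", "lambda", "lambda", "lambda",
    "lambda", "lambda", "lambda", "lambda", None,
)
SHAPE_EUTH = (
    "lambda", "lambda", None, "lambda", None,
    "lambda", None, None, None, None,
)
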