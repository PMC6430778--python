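"""Stage one child's radiograph and estimate a dental age two ways.

Builds a record for a boy with mixed tooth-development stages (one molar
readable only on the right side), computes his dental maturity score (DMS),
then converts it to an estimated dental age via the packaged conversion
table and via the bundled logistic prediction model.
"""

import datetime as dt

from dentalage import (
    DEFAULT_MODELS,
    ChildRecord,
    Stage,
    compute_dms,
    dms_to_age,
    packaged_conversion_table,
    packaged_score_table,
    predict_age,
)

record = ChildRecord(
    child_id="demo-001",
    sex="M",
    dob=dt.date(2010, 3, 1),
    dor=dt.date(2017, 9, 15),
    stages={
        31: Stage.H, 32: Stage.G, 33: Stage.F, 34: Stage.F,
        35: Stage.E, 37: Stage.D,
        46: Stage.F,  # left first molar unreadable: right side substitutes
    },
)

table = packaged_score_table()
record.dms = compute_dms(record, table)
eda_table = dms_to_age(record.dms, record.sex, packaged_conversion_table())
eda_model = predict_age(record.dms, DEFAULT_MODELS[record.sex])

print(f"chronological age (CA): {record.ca:.2f} years")
print(f"dental maturity score (DMS): {record.dms:.2f} / 100")
print(f"estimated dental age, conversion table: {eda_table:.2f} years")
print(f"estimated dental age, prediction model: {eda_model:.2f} years")
print(
    "A positive EDA-CA gap means the conversion standard calls this child "
    "dentally advanced for his calendar age."
)
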