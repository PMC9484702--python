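"""Encode two short proteins with E-descriptors and ACC-featurize them.

Each sequence, whatever its length, becomes the same fixed-length
125-dimensional vector: descriptor pair (j, k) crossed with lag 1..5.
"""

from alleracc import (ProteinRecord, SequenceDataset, acc_transform,
                      encode_sequence, featurize_dataset, load_e_descriptor_table)

table = load_e_descriptor_table()

short = ProteinRecord(id="short", sequence="MKVLWAALLVTFLAGCQA")
long = ProteinRecord(id="long", sequence="MKVLWAALLVTFLAGCQA" * 20)

for record in (short, long):
    encoded = encode_sequence(record, table)
    vec = acc_transform(encoded, max_lag=5)
    print(f"{record.id}: {record.length} residues -> {len(vec.values)} features")
    # AC111: autocovariance of E1 (hydrophilicity) at lag 1 — mean lagged
    # product of neighbouring residues' hydrophilicity scores
    print(f"  AC111 = {vec.values[list(vec.names).index('AC111')]: .5f}")
    print(f"  AC121 = {vec.values[list(vec.names).index('AC121')]: .5f}")

dataset = SequenceDataset(records=[short, long])
features = featurize_dataset(dataset, table)
print(f"batch matrix: {features.values.shape[0]} rows x "
      f"{features.values.shape[1]} columns, identical for any input lengths")
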