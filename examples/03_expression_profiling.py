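"""Differential expression between two libraries at the two-fold rule.

Normalizes raw counts to reads per million mappable reads (RPM) and
calls a miRNA differentially expressed when the larger/smaller RPM
ratio strictly exceeds 2.  The first row reproduces a published
comparison: 520 vs 3882 raw reads across libraries of 4,540,620 and
4,667,617 mappable reads give a 7.26-fold enrichment in library B.
Also shows qRT-PCR quantification by the 2^-ddCt rule.
"""

from stemloop.expression import ddct, de_table, fold_change, normalize_rpm

counts = {
    "bra-miR824-p3": (520, 3882),
    "bra-miR167b-p3": (6061, 3762),
    "bra-miR172a-p5": (8, 8),
}
records = normalize_rpm(counts, lib_size_A=4_540_620, lib_size_B=4_667_617)
calls = [fold_change(rec) for rec in records]
print(de_table(calls).to_string(index=False))

print()
rec = ddct(target_ct_test=18.0, ref_ct_test=15.0,
           target_ct_calibrator=20.0, ref_ct_calibrator=15.0)
print(f"qRT-PCR: ddCt = {rec.delta_delta_ct} cycles -> "
      f"relative expression 2^-ddCt = {rec.relative_expression}")
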