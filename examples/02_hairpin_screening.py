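"""Screen one precursor hairpin through the five miRNA/miRNA* criteria.

Folds a constructed precursor, evaluates the duplex geometry
(mismatches, bulges, 3' overhangs, arm placement) and the MFEI, and
prints the verdict.  MFEI = AMFE / GC% with AMFE = |MFE|/length*100;
genuine plant pre-miRNAs typically exceed the 0.8 screening threshold.
"""

import numpy as np

from stemloop.fold import fold
from stemloop.hairpin import classify_candidate, compute_metrics, evaluate_duplex
from stemloop.simulate import make_hairpin

rng = np.random.default_rng(8)
design = make_hairpin(rng, "true")

structure, mfe = fold(design["precursor"])
duplex = evaluate_duplex(structure, design["mir_span"], design["star_span"])
metrics = compute_metrics(mfe, sequence=design["precursor"])
verdict = classify_candidate(duplex, metrics, star_observed=True)

s, e = design["mir_span"]
print("mature   :", design["mature"])
print("star     :", design["star"])
print("structure:", structure)
print()
print(f"duplex: {duplex.mismatch_count} mismatches "
      f"(longest run {duplex.max_consecutive_mismatches}), "
      f"{duplex.asymmetric_bulge_count} asymmetric bulges, "
      f"3' overhangs {duplex.mir_3p_overhang}/{duplex.star_3p_overhang} nt")
r = metrics.rounded()
print(f"energy: MFE {r.mfe} kcal/mol over {len(design['precursor'])} nt, "
      f"GC {r.gc_percent}%, AMFE {r.amfe}, MFEI {r.mfei}")
print()
print("criteria:", ", ".join(f"{k}={'pass' if v else 'FAIL'}"
                             for k, v in verdict.flags.items()))
print("verdict :", "validated miRNA/miRNA* pair" if verdict.passed else "rejected")
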