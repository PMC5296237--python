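"""Score one week of self-report questionnaires and read off clinical bands.

A participant's weekly responses are scored to instrument totals; the totals
map to clinical severity bands (depression, anxiety) or a screening flag
(mania).
"""

from moodkit.questionnaires import (
    AsrmResponse,
    Gad7Response,
    QidsResponse,
    classify_asrm,
    classify_gad7,
    classify_qids,
    qids_domains,
    score_asrm,
    score_gad7,
    score_qids,
)

asrm = AsrmResponse((1, 2, 0, 1, 2))
qids = QidsResponse((1, 2, 0, 0, 2, 1, 0, 0, 0, 2, 1, 0, 2, 1, 1, 0))
gad7 = Gad7Response((2, 1, 2, 1, 1, 0, 1))

asrm_total = score_asrm(asrm)
qids_total = score_qids(qids)
gad7_total = score_gad7(gad7)

print(f"ASRM total {asrm_total}/20 -> manic episode flag: "
      f"{classify_asrm(asrm_total)}")
print(f"QIDS domains: {qids_domains(qids)}")
print(f"QIDS total {qids_total}/27 -> band: {classify_qids(qids_total).band}")
print(f"GAD-7 total {gad7_total}/21 -> band: {classify_gad7(gad7_total).band}")
# The QIDS total sums nine domain scores (sleep, appetite/weight and
# restlessness take the max of their item blocks), not the 16 raw items.
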