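"""Encode one RNA hairpin as a TV-curve and inspect the signal.

The hairpin GGGGAAAACCCC folds into a 4-pair stem with a 4-base loop.
Paired bases become primed symbols; each symbol contributes three +/-1
vertical steps, so the curve has 3N+1 points starting at the origin.
"""

from tvcurve import NussinovBackend, RnaRecord, encode_tvcurve

rec = RnaRecord(id="hairpin", sequence="GGGGAAAACCCC")
backend = NussinovBackend()
curve = encode_tvcurve(rec, backend=backend)

print(f"sequence   : {rec.sequence}")
print(f"structure  : {backend.fold(rec.sequence)}")
print(f"symbols    : {' '.join(str(s) for s in curve.decode())}")
print(f"steps (3N) : {curve.steps.tolist()}")
print(f"endpoint   : {tuple(int(v) for v in curve.points[-1])}")
# The endpoint y-value is the sum of all steps; the decoded symbol string
# shows primed (paired) vs unprimed (unpaired) bases — the encoding is
# lossless, so the curve alone determines sequence and pairing state.
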