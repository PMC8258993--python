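"""Exact enrichment test of a MURK list against an independent response set.

Uses the published comparison counts - 55 of 89 screened genes fall among the
1022 strongest Gata1-induction responders out of a 4195-gene universe - and
computes the exact upper-tail hypergeometric probability in log space, plus
the fold enrichment over the chance expectation.
"""

from murkscreen import OverlapInputs, hypergeom_tail

inputs = OverlapInputs(m=55, n=89, A=1022, N=4195)
res = hypergeom_tail(inputs)

print(f"observed overlap   : {inputs.m} of {inputs.n}")
print(f"expected by chance : {res.expected_overlap:.2f}")
print(f"fold enrichment    : {res.fold_enrichment:.2f}")
print(f"P(X >= {inputs.m})         : {res.p_value:.3e}  (log10 p = {res.log10_p:.2f})")
print(
    "\nAn overlap 2.5x above chance with p ~ 1e-13: the screened genes are"
    "\nmassively enriched among genes that respond to Gata1 induction."
)
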