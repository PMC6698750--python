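"""The five-variant LITer1.0-vs-LITer2.0 basal-expression comparison.

Reproduces the model experiment asking whether merging the two-promoter
circuit into one polycistronic promoter lowers basal (dark-state) leakage:
with fully equal parameters the architectures are equivalent; letting
DNA-bound TetR degrade, or giving TetR weaker transcription/translation
than GFP (as in the real two-promoter construct), makes the two-promoter
circuit leakier — which is the rationale for the LITer2.0 design.
"""

from litersim import RateParams, run_full_comparison
from litersim.comparison import comparison_table

reports, verdict = run_full_comparison(RateParams(), engine="deterministic")
table = comparison_table(reports)
print(table[["variant", "basal_liter1", "basal_liter2", "ratio"]].to_string(index=False,
      float_format=lambda v: f"{v:9.3f}"))
print()
for key, ok in verdict.items():
    print(f"  {key:40s} {'PASS' if ok else 'FAIL'}")
print()
print("ratio = liter1 basal / liter2 basal. Ratios > 1 mean the two-promoter")
print("circuit leaks more; the combined variant exceeds either single change.")
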