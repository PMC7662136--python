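"""End-to-end scenario comparison: schools closed versus schools open.

Runs the full Monte Carlo model on the default synthetic inputs and prints
the per-discount-rate summaries and exceedance probabilities. 20,000 draws
take well under a minute on one CPU; raise n_draws for smoother tails.
"""

import schoolyll as sy

report = sy.run_full_model(sy.ModelParams(n_draws=20_000, seed=1))

print(f"reported deaths:       {report.reported_deaths:,}")
print(f"direct YLL:            {report.base_direct_yll/1e6:.2f} million person-years")
d = report.direct_summary
print(f"corrected direct YLL:  {d.median/1e6:.2f}M ({d.ci_low/1e6:.2f}-{d.ci_high/1e6:.2f})")
o = report.open_summary
print(f"schools-open YLL:      {o.median/1e6:.2f}M ({o.ci_low/1e6:.2f}-{o.ci_high/1e6:.2f})")
for rate, s in report.education_summaries.items():
    print(
        f"education YLL @ {rate:>5.1%}: {s.median/1e6:.2f}M "
        f"({s.ci_low/1e6:.2f}-{s.ci_high/1e6:.2f})  "
        f"P(closed worse) = {report.exceedance[rate]:.1%}"
    )
report.save("full_comparison_out", plot=True)
print("wrote full_comparison_out/{summary.csv, report.json, densities.png}")
# Undiscounted, the education-mediated losses (~6-7M person-years) dwarf
# the extra direct deaths a reopening might have caused (~1.4M), so school
# closure is the worse scenario in ~99% of draws; at a 3% discount rate the
# far-future education losses shrink and the comparison becomes a coin flip.
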