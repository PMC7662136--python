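"""Direct years of life lost from the bundled age-banded death table.

Sums deaths x remaining life expectancy per 10-year age band, then corrects
the total for death underreporting with a PERT-distributed ratio.
"""

import numpy as np

import schoolyll as sy

table = sy.builtin_death_table()
total, rows = sy.yll_from_deaths(table)

print(f"reported deaths:            {sy.total_deaths(table):,}")
print(f"direct YLL (person-years):  {total:,.0f}")

draws = sy.corrected_direct_yll(total, n=100_000, seed=1)
s = sy.summarize_draws(draws)
print(
    f"undercount-corrected YLL:   {s.median/1e6:.2f} million "
    f"(95% CI {s.ci_low/1e6:.2f}-{s.ci_high/1e6:.2f})"
)
# The ~88k deaths reported through early June 2020 cost ~1.15M life-years
# outright; allowing for underreported deaths (ratio mode 1.22, max 2.44)
# the central estimate rises to ~1.5M person-years.
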