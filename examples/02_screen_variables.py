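"""Screen candidate variables for agreement-analysis eligibility.

The showcase fixture contains, by construction, one variable failing
each eligibility rule (no repeats, too few distinct integer values,
too many ties, too few repeat pairs) plus clean continuous variables —
so the expected verdicts are known exactly.
"""

from regdilute import generate_showcase_table, screen_table

fixture = generate_showcase_table(seed=0)
decisions, counts = screen_table(fixture.table)

print(f"{'variable':<14}{'verdict':<10}{'reason':<18}{'pairs':>6}{'distinct':>9}")
for d in decisions:
    print(f"{d.variable:<14}{d.verdict:<10}{d.reason:<18}"
          f"{d.n_repeat_pairs:>6}{d.distinct_count:>9}")
print("\ncounts by reason:", counts)
# A variable is analysed only when reason == 'ok': it is continuous
# (integer-coded measures need >20 distinct values), no single value is
# shared by >20% of participants, and >=100 repeat pairs exist.
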