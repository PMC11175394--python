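"""Reproduce the printed registry tables from the packaged cell counts.

The packaged fixtures hold the published origin-destination cell counts and
demographic counts (cells only, no totals). All percentages are re-derived
from the counts with half-away one-decimal rounding and printed next to
the headline values they reproduce.
"""

from hivcanlink.config import load_demographics_fixture, load_od_fixture
from hivcanlink import tables

od = tables.OriginDestinationMatrix.from_counts(load_od_fixture())
pct = od.column_percentages()

print(f"study population (cell total): {od.total():,}")
print(f"diagnosed outside home province: {od.off_diagonal_total():,} "
      f"({100 * od.off_diagonal_total() / od.total():.1f}%)")
print(f"Gauteng diagnosed the most cancers: {od.row_totals()['GAU']:,}")
print(f"Western Cape keeps {pct.loc['WC', 'WC']}% of its patients in "
      "province;")
print(f"KwaZulu-Natal keeps only {pct.loc['KZN', 'KZN']}%, sending "
      f"{pct.loc['GAU', 'KZN']}% to Gauteng.")

shares = tables.destination_shares(od)
print(f"of all travellers, {100 * shares['GAU']:.1f}% were diagnosed in "
      "Gauteng")

demo = tables.demographics_from_counts(
    load_demographics_fixture()).set_index(["characteristic", "level"])
print(f"\nBlack patients diagnosed outside their province: "
      f"{demo.loc[('ethnicity', 'Black'), 'pct_outside']}%")
print(f"male patients diagnosed within their province: "
      f"{demo.loc[('gender', 'Male'), 'pct_within']}%")

bt = demo.loc["black_vs_nonblack"]
stat, df, p = tables.chi_square(bt[["outside", "within"]].to_numpy())
print(f"Black vs non-Black × location: chi² = {stat:.1f}, df = {df}, "
      f"p = {p:.2e}")
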