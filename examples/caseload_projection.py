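"""Project expected numbers of falsely interpreted cases worldwide.

The model multiplies a global caseload (10 million second-generation
kit cases) by the related/unrelated split (72%/28%), the case-type mix
(75% trio, 20% parent-child, 5% full-sibling), the fraction of
laboratories using each LR threshold, and the false rate of that cell.
Related-arm rows are false negatives (related called unrelated),
unrelated-arm rows false positives.
"""

from kinerr import project, table1_identifiler

model = table1_identifiler()
table = project(model)

print(f"total caseload: {model.total_cases:,} "
      f"({model.related_fraction:.0%} truly related)")
print(f"{'case type':>14s} {'arm':>10s} {'LR thr':>7s} {'labs':>5s} "
      f"{'rate':>8s} {'expected':>9s}")
for row in table.rows:
    print(f"{row.case_type:>14s} {row.arm:>10s} {row.threshold:>7g} "
          f"{row.lab_fraction:>5.0%} {row.false_rate:>8.4%} {row.count:>9,d}")
print(f"\ngrand total (sum of rounded rows):   {table.sum_of_rounded_rows:,}")
print(f"grand total (unrounded sum, rounded): {table.grand_total:,}")
# over 60,000 of 10 million cases projected wrongly concluded; the bulk
# are related individuals excluded in parent-child and sibling testing
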