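"""Compute the four evaluation ratios from a known answer partition.

Feeds a concrete partition of screened concepts against a 16-known /
8-seed risk registry through the ratio computation and prints both the
raw fractions and the display strings (truncated percents for
RKRR/SKRR, truncated two-decimal ratios for SSRR/SUAR).
"""

from crowdscreen import PartitionCounts, compute_ratios

partition = PartitionCounts(
    known_total=16,                # known risks in the registry
    known_answered=13,             # knowns the crowd re-proposed (8 seeds + 5)
    known_answered_significant=8,  # of those, significant on OVERALL
    seed_total=8,                  # seed questions planted in round 1
    seed_significant=4,            # seeds confirmed significant
    unknown_significant=53,        # significant non-registry concepts
    significant_total=61,          # all significant concepts (53 + 8)
)

report = compute_ratios(partition)
for name, raw, shown in [
    ("RKRR", report.rkrr, report.formatted()["rkrr"]),
    ("SKRR", report.skrr, report.formatted()["skrr"]),
    ("SSRR", report.ssrr, report.formatted()["ssrr"]),
    ("SUAR", report.suar, report.formatted()["suar"]),
]:
    print(f"{name}: {raw:.4f}  ->  {shown}")
# High RKRR: the crowd rediscovers most known risks. SUAR near 1: most
# significant findings are outside the registry, i.e. candidate novelty.
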