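"""Screen one candidate factor: 2x2 table, odds ratio, Woolf interval.

Builds a small questionnaire extract by hand, tallies the
exposure-by-disease table for the asthma stratum and prints the odds
ratio with its 95% confidence interval.  The factor is flagged
significant only when the lower bound exceeds 1.0.
"""

from crowdscreen import ParticipantResponse, build_table, odds_ratio

responses = []
# 40 participants: exposure is enriched among asthma cases.
for i in range(40):
    case = i < 12
    exposed = (i % 3 == 0) if not case else (i % 3 != 0)
    responses.append(
        ParticipantResponse(
            participant_id=f"p{i:02d}",
            round_index=1,
            allergy_flags={"asthma": case},
            answers={"q_mold": "yes" if exposed else "no"},
        )
    )

table = build_table(responses, "asthma", "q_mold")
result = odds_ratio(table)

print(f"table (a, b, c, d) = {table.cells}")
print(f"odds ratio         = {result.or_point:.2f}")
print(f"95% CI             = ({result.ci_low:.2f}, {result.ci_high:.2f})")
print(f"significant        = {result.significant}")
# The odds ratio compares the odds of exposure between cases and
# controls; 'significant' means the interval excludes 1 from above.
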