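"""Score IPAQ and MAAS responses to MET-min/week and activity categories."""

from metbout import QuestionnaireResponse, ResponseItem, ipaq_rules, maas_rules, score_response

ipaq = QuestionnaireResponse(
    "P001",
    "IPAQ",
    "followup",
    [
        ResponseItem("leisure", "vigorous", 3, 30.0),   # 3 d x 30 min at 8.0 MET
        ResponseItem("leisure", "walking", 5, 40.0),    # 5 d x 40 min at 3.3 MET
        ResponseItem("domestic", "moderate", 2, 300.0), # capped at 180 min/day
    ],
)
score = score_response(ipaq, ipaq_rules())
print(
    f"IPAQ:  {score.total_met_minutes_per_week:7.1f} MET-min/week over "
    f"{score.total_sessions_per_week} sessions -> {score.category} "
    f"(ln score {score.ln_score:.2f})"
)

maas = QuestionnaireResponse(
    "P001",
    "MAAS",
    "followup",
    [
        ResponseItem("leisure", "moderate", 4, 50.0),  # 200 weighted min
        ResponseItem("leisure", "vigorous", 2, 50.0),  # 100 min, double-weighted
    ],
)
score = score_response(maas, maas_rules())
print(
    f"MAAS:  {score.total_met_minutes_per_week:7.1f} MET-min/week over "
    f"{score.total_sessions_per_week} sessions -> {score.category}"
)
# The continuous total weights each item's minutes x days by its MET
# value; the category applies the instrument's occasion/minute rules
# (here IPAQ reaches 'high' via vigorous activity on >= 3 days with a
# total >= 1500 MET-min/week, and MAAS via >= 300 weighted minutes over
# >= 5 sessions).
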