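"""Score the deployed PRO instruments and summarize a joint-pain map.

Shows the three validated instruments (HAQ-DI, FACIT-Fatigue, EQ-5D-5L)
on hand-written responses, plus per-joint counts on the 55-joint map.
"""

from siteless import (JointPainMap, eq5d_profile, max_wrist_severity,
                      painful_joint_count, score_facitf, score_haqdi)

# HAQ-DI: first category {1, 0} but aids were used (raises it to 2),
# the other seven categories all zero -> (2 + 0*7) / 8 = 0.25
haq = score_haqdi([1, 0] + [0] * 18, aids_flags=[True] + [False] * 7)
print(f"HAQ-DI: {haq:.2f}  (0 = no disability, 3 = severe disability)")

# FACIT-Fatigue: mid-range responses everywhere
facit = score_facitf([2] * 13)
print(f"FACIT-Fatigue: {facit:.1f}  (0 = worst fatigue, 52 = none)")

profile, vas, _ = eq5d_profile([2, 1, 2, 3, 2], vas=70)
print(f"EQ-5D-5L profile {profile}, VAS {vas}  "
      "(each digit: one dimension, 1 = no problems .. 5 = extreme)")

pain_map = JointPainMap(participant_id="demo", week=1, scores={
    "right_wrist": 3, "left_wrist": 1, "left_knee": 2, "right_mcp2": 1})
print(f"painful joints (any severity): {painful_joint_count(pain_map)}")
print(f"moderate or worse: {painful_joint_count(pain_map, min_severity=2)}")
print(f"right wrist severity: {max_wrist_severity(pain_map, 'right')} "
      "(0 none, 1 mild, 2 moderate, 3 severe)")
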