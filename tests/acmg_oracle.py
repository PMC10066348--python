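"""Independent rule-list implementation of the ACMG combining rules.

This is the cross-check oracle for the point-based engine: the classic
criteria-combination table (counts of very strong / strong / moderate /
supporting evidence on each side) amended with the three rules the pipeline
pins — a very strong plus a moderate criterion is pathogenic, two strong
criteria alone are likely pathogenic, and PVS1 with supporting-strength PM2
alone is likely pathogenic. It is deliberately written in terms of
count-combination rules, sharing no code with the point engine.
"""

from __future__ import annotations

#: The strength each criterion carries in this pipeline.
FIXED_STRENGTHS = {
    "PVS1": "very_strong",
    "PS1": "strong", "PS3": "strong", "PS4": "strong",
    "PM1": "moderate", "PM2": "supporting", "PM4": "moderate", "PM5": "moderate",
    "PP1": "supporting", "PP2": "supporting", "PP3": "supporting",
    "BA1": "stand_alone",
    "BS1": "strong", "BS3": "strong", "BS4": "strong",
    "BP3": "supporting", "BP4": "supporting", "BP7": "supporting",
}

BENIGN_SIDE = frozenset({"BA1", "BS1", "BS3", "BS4", "BP3", "BP4", "BP7"})


def rule_list_classify(criteria: frozenset[str] | set[str]) -> str:
    """Five-tier class from the amended count-combination rules."""
    names = set(criteria)
    nvs = sum(1 for c in names if c not in BENIGN_SIDE
              and FIXED_STRENGTHS[c] == "very_strong")
    ns = sum(1 for c in names if c not in BENIGN_SIDE
             and FIXED_STRENGTHS[c] == "strong")
    nm = sum(1 for c in names if FIXED_STRENGTHS[c] == "moderate")
    np_ = sum(1 for c in names if c not in BENIGN_SIDE
              and FIXED_STRENGTHS[c] == "supporting")
    nbs = sum(1 for c in names if c in BENIGN_SIDE
              and FIXED_STRENGTHS[c] == "strong")
    nbp = sum(1 for c in names if c in BENIGN_SIDE
              and FIXED_STRENGTHS[c] == "supporting")

    if "BA1" in names:
        return "benign"

    path = None
    if ((nvs >= 1 and (ns >= 1 or nm >= 2 or (nm == 1 and np_ >= 1) or np_ >= 2))
            or ns >= 2
            or (ns == 1 and (nm >= 3 or (nm == 2 and np_ >= 2)
                             or (nm == 1 and np_ >= 4)))):
        path = "pathogenic"
    elif ((nvs == 1 and nm == 1) or (ns == 1 and 1 <= nm <= 2)
          or (ns == 1 and np_ >= 2) or nm >= 3
          or (nm == 2 and np_ >= 2) or (nm == 1 and np_ >= 4)):
        path = "likely_pathogenic"

    # the three amendments
    if nvs >= 1 and nm >= 1:
        path = "pathogenic"
    if ns == 2 and nvs == 0 and nm == 0 and np_ == 0:
        path = "likely_pathogenic"
    if names == {"PVS1", "PM2"}:
        path = "likely_pathogenic"

    benign = None
    if nbs >= 2:
        benign = "benign"
    elif (nbs == 1 and nbp >= 1) or nbp >= 2:
        benign = "likely_benign"

    if path and benign:
        return "vus"
    return path or benign or "vus"
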