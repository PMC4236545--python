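"""Generate a synthetic township survey and write its CSV files.

The generator emulates a complete-population survey of a rural township of
older adults: a roster of residents aged 60+ and their spouses, one
ego-network questionnaire per respondent (spouse roster + up to five
discussion alters, with noisy name/age reports), and the alter-alter
acquaintance matrix.  It also returns the planted ground truth used to
score entity resolution downstream.
"""

from villagenet import TownshipConfig, generate_township, validate_survey, write_survey_csv

cfg = TownshipConfig(n_population=860, seed=1)
roster, surveys, truth = generate_township(cfg)
write_survey_csv(roster, surveys, "scratch/example_township")

n_married = sum(1 for p in roster if p.marital_status == "living_with_spouse")
n_reports = sum(len(s.members) for s in surveys)
print(f"roster persons:        {len(roster)}")
print(f"respondents surveyed:  {len(surveys)}")
print(f"living with spouse:    {n_married} ({n_married / len(roster):.0%})")
print(f"alter reports:         {n_reports}")
print(f"distinct true persons: {len(set(truth.identity_map.values()))}")
print(f"schema violations:     {len(validate_survey(roster, surveys))}")
# The report count exceeds the distinct-person count because popular
# residents are named by several egos - the duplicates entity resolution
# must merge.
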