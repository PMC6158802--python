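# Controlled biomedical English grammar for treatment rationales.
#
# One rule per line: "LHS -> sym sym ...".  The LHS of the first rule is
# the start symbol.  Symbols:
#   @CAT       matches a lexical unit bound to a lexicon concept of that
#              category (DRUG, GENE, ALTERATION, DISEASE, PROCEDURE, FOOD);
#              an unknown NOUNISH unit also matches, at a fallback cost.
#   %NUMBER    matches a number token.
#   %CITATION  matches a parenthesized citation token.
#   anything else is a terminal matched case-insensitively against the
#   unit's surface text.
# A symbol that looks like a non-terminal (ALL-CAPS, no @/% prefix) but is
# never defined draws a load-time warning, not an error.

S -> TRIAL_TR
S -> CASE_TR
S -> SIMPLE_TR
S -> SIMPLE_TR .

# "<biomarker> in <disease> confers <effect> to <drug>, as demonstrated in
#  a <trial-type> with <N> patients with <stage> <disease> (<citation>)"
TRIAL_TR -> SIMPLE_TR , EVIDENCE_CLAUSE
TRIAL_TR -> SIMPLE_TR , EVIDENCE_CLAUSE %CITATION
TRIAL_TR -> SIMPLE_TR , EVIDENCE_CLAUSE .

EVIDENCE_CLAUSE -> as demonstrated in a TRIALPHRASE
EVIDENCE_CLAUSE -> as demonstrated in a TRIALPHRASE NPATIENTS
EVIDENCE_CLAUSE -> as demonstrated in a TRIALPHRASE NPATIENTS with POPULATION
EVIDENCE_CLAUSE -> as shown in a TRIALPHRASE
EVIDENCE_CLAUSE -> as shown in a TRIALPHRASE NPATIENTS
EVIDENCE_CLAUSE -> as shown in a TRIALPHRASE NPATIENTS with POPULATION

NPATIENTS -> with %NUMBER patients
POPULATION -> STAGE @DISEASE
POPULATION -> @DISEASE

# Declarative core forms.
SIMPLE_TR -> BIOMARKER in @DISEASE confers EFFECT to DRUGS
SIMPLE_TR -> BIOMARKER confers EFFECT to DRUGS in @DISEASE
SIMPLE_TR -> BIOMARKER confers EFFECT to DRUGS

EFFECT -> sensitivity
EFFECT -> resistance

DRUGS -> @DRUG
DRUGS -> @DRUG and DRUGS

BIOMARKER -> @GENE @ALTERATION
BIOMARKER -> @ALTERATION
BIOMARKER -> @GENE

# Single-patient case narrative:
# "This <age> year old <sex>'s stage <k> <disease> tumor was apparently
#  sensitized to <drug> by a(n) <biomarker>."
CASE_TR -> this AGE SEXPOSS STAGE @DISEASE tumor was EFFECTED_P to @DRUG by DET BIOMARKER .
CASE_TR -> this AGE SEXPOSS @DISEASE tumor was EFFECTED_P to @DRUG by DET BIOMARKER .

AGE -> %NUMBER year old
SEXPOSS -> male's
SEXPOSS -> female's
STAGE -> stage %NUMBER
EFFECTED_P -> EFFECTED
EFFECTED_P -> ADV EFFECTED
EFFECTED -> sensitized
EFFECTED -> made resistant
ADV -> apparently
ADV -> presumably
DET -> a
DET -> an

TRIALPHRASE -> randomized controlled trial
TRIALPHRASE -> meta-analysis of randomized trials
TRIALPHRASE -> meta-analysis
TRIALPHRASE -> phase PHASENUM trial
TRIALPHRASE -> phase PHASENUM clinical trial
TRIALPHRASE -> case report
TRIALPHRASE -> clinical series
TRIALPHRASE -> cell line study
TRIALPHRASE -> mouse model study
TRIALPHRASE -> in vitro study
TRIALPHRASE -> in vivo study
PHASENUM -> i
PHASENUM -> ii
PHASENUM -> iii
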