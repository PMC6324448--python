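role	text
# {T} is replaced by a target surface form; the gold mention span is the
# span of that substitution. Present templates must not contain any
# modifier trigger; distractors must not contain any target term.
present	Patient presents with {T}.
present	Active {T} noted on exam.
present	Ongoing {T} requiring transfusion.
present	Repeat imaging shows {T}.
present	New {T} this morning.
present	Large {T} over the left flank.
present	{T} observed at the surgical site.
negated	Patient denies {T}.
negated	No {T} noted.
negated	Exam negative for {T}.
negated	Without evidence of {T}.
historical	History of {T} several years ago.
historical	Prior {T} documented in outside records.
historical	Remote {T} per family.
hypothetical	Transfuse if {T} recurs.
hypothetical	Monitor for {T} overnight.
hypothetical	Risk of {T} discussed with patient.
hypothetical	Will transfuse should {T} develop.
distractor	Vital signs stable.
distractor	Continue home medications.
distractor	Lungs clear to auscultation.
distractor	Afebrile overnight.
distractor	Tolerating regular diet.
distractor	Creatinine stable at baseline.
distractor	Chest radiograph unremarkable.
distractor	Electrolytes repleted this morning.
distractor	Follow up with primary care in two weeks.
distractor	Seen by [**Name**] on [**2101-4-12**].
adversarial	We discussed {T} at length.|None has occurred during this stay.
adversarial	Counseling provided regarding {T}.|The patient understood the plan.
pmh_item	- HTN
pmh_item	- Type 2 diabetes
pmh_item	- CKD stage 2
pmh_item	- Osteoarthritis
pmh_item	- Hyperlipidemia
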