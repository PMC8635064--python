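# Relationship word -> category map (editable configuration, tab-separated).
# Plural forms fold onto these entries by s-stripping.
husband	spouse
wife	spouse
spouse	spouse
partner	spouse
child	children
children	children
son	children
daughter	children
kid	children
stepson	children
stepdaughter	children
grandchild	grandchildren
grandchildren	grandchildren
grandson	grandchildren
granddaughter	grandchildren
grandkid	grandchildren
sister	sibling
brother	sibling
sibling	sibling
mother	parent
father	parent
mom	parent
dad	parent
parent	parent
friend	friend
buddy	friend
pal	friend
neighbor	friend
niece	other_family
nephew	other_family
cousin	other_family
aunt	other_family
uncle	other_family
family	other_family
doctor	professional
nurse	professional
caregiver	professional
therapist	professional
pastor	professional
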