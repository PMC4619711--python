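drug	external_id	categories	description
cisplatin	DB00515	Antineoplastic Agents;Platinum Compounds	Platinum-based chemotherapy drug used against several cancers; toxicity varies with host genotype.
warfarin	DB00682	Anticoagulants	Vitamin K antagonist anticoagulant with a narrow therapeutic index and strongly genotype-dependent dosing.
phenprocoumon	DB00946	Anticoagulants	Long-acting coumarin anticoagulant related to warfarin.
clopidogrel	DB00758	Platelet Aggregation Inhibitors	Antiplatelet prodrug activated by CYP2C19; poor metabolizers gain reduced protection.
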