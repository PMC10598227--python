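# Intermolecular protein-ligand distance restraints (TSV dialect)
# columns: residue_token protein_hydrogen ligand_hydrogen upper_A
F71	HE*	HM*	4.5
F71	HZ	HM*	3.3
F71	HZ	HN*	6
M74	HE*	HK*	6.5
M74	HE*	HL*	4.5
M74	HE*	HM*	6
L78	HD1*	H4	5.5
L78	HD1*	HF*	4.5
L78	HD1*	HG*	4.5
L78	HD2*	H4	6.5
L78	HD2*	HF*	6.5
L78	HD2*	HG*	6.5
L78	HD2*	HH*	6
L80	HD1*	HF*	3.8
L80	HD1*	HG*	4.5
L80	HD2*	HF*	6.5
A85	HB*	HF*	4.5
A85	HB*	HG*	6.5
R88	HA	HJ*	6
R88	HB*	HF*	4.5
R88	HB*	HG*	4.5
R88	HB*	HI*	4.5
T91	HB	HJ*	4
T91	HG2*	H9	5.5
T91	HG2*	HJ*	3.8
V92	HG1*	HK*	4.5
V92	HG1*	HL*	3.8
V92	HG1*	HM*	6
V92	HG1*	HN*	3.8
V92	HG2*	HF*	4.5
V92	HG2*	HG*	3.8
V92	HG2*	HI*	3.8
V92	HG2*	HJ*	6.5
L96	HD1*	H23	5.5
A108	HB2	H23	5.5
A108	HB*	HM*	6.5
F112	HB*	HM*	6.5
F112	HN	HM*	4
F112	HN	HN*	4
F112	HZ	HF*	3.3
F112	HZ	HG*	4
M116	HE*	HF*	6.5
M116	HE*	HG*	6.5
F171	HZ	H23	3.5
F171	HZ	HM*	5.5
F171	HZ	HN*	4
W173	HE1	HK*	7
W173	HE1	HL*	4
L174	HD1*	H23	5.5
L176	HB*	HH*	5
L176	HD1*	HH*	6
L176	HD1*	HI*	4.5
L176	HD1*	HJ*	6.5
L176	HD1*	HK*	6.5
L176	HD2*	HH*	4.5
L176	HD2*	HI*	4.5
L176	HD2*	HJ*	4.5
L176	HD2*	HK*	6.5
L176	HN	HK*	6
L176	HN	HL*	4
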