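challenge	SAP	CFa	CFm	REG1d	CBF	LDF	ICP	CVP	PAP	CO2	pO2
iso-prop transit	+	-	-	-	-	+	-	-	+/-	0	-
PEEP 10	-	+	-	+	+	-	+	-	0	+	-
PEEP 15	-	+	-	+	+/-	+	+	-	0	+	-
PEEP 20	-	+	-	+	+/-	+	+	-	-	+	-
hemorrhage 1	-	+	-	+	+	+	-/+	+	+	-	-/+
PEEP 10	0	0	-/+	+	0	0	+	-	-	+	-
PEEP 15	-	-/+	-/+	+	+	0	+	-	-	+	-
PEEP 20	-	-/+	-/+	+	-/+	-/+	+	-	+	+	-
CO2 inhalation	+	0	0	0	+	0	+	0	-	+	-
hemorrhage 2	-	+	+/-	+	-	0	-	+	+	0	+/0
PEEP 10	0	0	+	-	+	0	+	-	-	+	-
PEEP 15	+	-	+	-	+	0	+	+	-	+	-
PEEP 20	-/+	-	-	-	+	+	+	+	-	+	-
hemorrhage 3	-	+	-	+	+	0	-	-	-	+	0
PEEP 10	+	0	0	0	0	0	+	+/-	+	+	+
lethal bleeding	-	+/-	-	+/-	-	-	-	-/+	+/-	-/+	+/-
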