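id	parent	start	end	partner	outcome	note
QQS-1-12	QQS	1	12	AtNF-YC4	binds	MBP pull-down; GST reciprocal failed, likely bait masking of the 12-aa peptide
QQS-11-59	QQS	11	59	AtNF-YC4	binds	MBP and GST pull-downs
QQS-13-47	QQS	13	47	AtNF-YC4	no_binding	MBP pull-down
QQS-41-59	QQS	41	59	AtNF-YC4	binds	MBP and GST pull-downs
QQS-48-59	QQS	48	59	AtNF-YC4	no_binding	MBP pull-down
QQS-1-12	QQS	1	12	HsNF-YC-1-145	binds	MBP pull-down
QQS-11-59	QQS	11	59	HsNF-YC-1-145	binds	MBP and GST pull-downs
QQS-13-47	QQS	13	47	HsNF-YC-1-145	not_tested
QQS-41-59	QQS	41	59	HsNF-YC-1-145	binds	MBP and GST pull-downs
QQS-48-59	QQS	48	59	HsNF-YC-1-145	not_tested
QQS-1-12	QQS	1	12	HsNF-YC	no_binding	GST reciprocal only; failure attributed to bait masking
QQS-11-59	QQS	11	59	HsNF-YC	binds	GST pull-down
QQS-41-59	QQS	41	59	HsNF-YC	binds	GST pull-down
QQS-13-47	QQS	13	47	HsNF-YC	not_tested
QQS-48-59	QQS	48	59	HsNF-YC	not_tested
HsNF-YC-1-145	HsNF-YC	1	145		not_tested	N-terminal construct carrying the conserved histone-fold region
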