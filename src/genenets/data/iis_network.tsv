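gene_a	gene_b	interaction_class	evidence_class	publications
daf-16	daf-2	physical	experimental	P0001|P0002|P0003|P0004|P0005|P0006|P0007|P0008|P0009|P0010|P0011|P0012|P0013|P0014|P0015|P0016|P0017|P0018|P0019|P0020|P0021|P0022|P0023|P0024|P0025|P0026|P0027|P0028|P0029|P0030|P0031|P0032|P0033|P0034|P0035|P0036|P0037|P0038|P0039|P0040|P0041|P0042|P0043|P0044|P0045|P0046|P0047|P0048|P0049|P0050|P0051|P0052|P0053|P0054|P0055|P0056|P0057|P0058|P0059|P0060|P0061|P0062|P0063|P0064|P0065|P0066|P0067|P0068|P0069|P0070|P0071|P0072|P0073|P0074|P0075|P0076|P0077|P0078|P0079|P0080|P0081|P0082|P0083|P0084|P0085|P0086|P0087|P0088|P0089|P0090|P0091|P0092|P0093|P0094|P0095|P0096|P0097|P0098|P0099|P0100|P0101|P0102|P0103|P0104|P0105|P0106|P0107|P0108|P0109|P0110|P0111|P0112|P0113|P0114|P0115|P0116|P0117|P0118|P0119|P0120|P0121|P0122|P0123|P0124|P0125|P0126|P0127|P0128|P0129|P0130|P0131|P0132|P0133|P0134|P0135
daf-3	daf-16	genetic	experimental	P1001
peb-1	daf-16	physical	experimental	P1002
myo-2	daf-16	physical	experimental	P1003
daf-36	daf-16	genetic	experimental	P1004
daf-2	daf-36	genetic	experimental	P1005
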