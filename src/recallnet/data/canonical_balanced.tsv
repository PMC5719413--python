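source	target	valence	label
Alyssa	Anne	+1	
Alyssa	James	+1	
Alyssa	Oliver	-1	
Alyssa	Thomas	+1	
Catherine	Grace	+1	
Catherine	Lewis	+1	
Catherine	Margaret	+1	
Catherine	Peter	-1	
Elizabeth	Henry	+1	
Elizabeth	James	+1	
Grace	Lewis	+1	
Grace	Peter	-1	
Grace	Victoria	+1	
Henry	James	+1	
Isabelle	Margaret	-1	
Isabelle	Samuel	-1	
Lewis	Margaret	+1	
Lewis	Peter	-1	
Lewis	Samuel	+1	
Margaret	Peter	-1	
Margaret	Victoria	+1	
Peter	Samuel	-1	
Samuel	Victoria	+1	
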