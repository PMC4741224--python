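act	ipni	index_fungorum	mycobank	zoobank
new_taxon/suprafamilial	-	+	+
new_taxon/familial	+	+	+	+
new_taxon/infrafamilial	+	+	+	+
new_taxon/generic	+	+	+	+
new_taxon/infrageneric	+	+	+	+
new_taxon/specific	+	+	+	+
new_taxon/infraspecific	+	+	+	+
new_taxon/hybrid	+	+	+	n/a
new_replacement_name	+	+	+
new_combination	+	+	+
tautonym	+	+	+	n/a
typification/holotype	+	+	+
typification/lectotype	-	+	+
typification/neotype	-	+	+
typification/epitype	-	+	+	n/a
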