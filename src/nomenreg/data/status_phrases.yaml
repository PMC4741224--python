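# Status-phrase vocabulary mapping the phrase printed in a nomenclature
# block to an act classification. Kept as config rather than code because
# journals vary in the phrases they print. The shipped vocabulary carries
# exactly one phrase per classification (injective); journals adding
# synonyms (e.g. "var. nov.", "trib. nov.") extend this file.
"sp. nov.": {kind: new_taxon, rank: specific}
"gen. nov.": {kind: new_taxon, rank: generic}
"subgen. nov.": {kind: new_taxon, rank: infrageneric}
"fam. nov.": {kind: new_taxon, rank: familial}
"subfam. nov.": {kind: new_taxon, rank: infrafamilial}
"ord. nov.": {kind: new_taxon, rank: suprafamilial}
"subsp. nov.": {kind: new_taxon, rank: infraspecific}
"comb. nov.": {kind: new_combination}
"nom. nov.": {kind: new_replacement_name}
"holotype designated": {kind: typification, type_kind: holotype}
"lectotype designated": {kind: typification, type_kind: lectotype}
"neotype designated": {kind: typification, type_kind: neotype}
"epitype designated": {kind: typification, type_kind: epitype}
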