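# Registrability of nomenclatural acts per registry, one row per act
# descriptor. Values: recorded | not_recorded | not_applicable.
# A cell marked table_blank was left blank in the printed source table and
# is transcribed as recorded (the governing code covers the act and the
# registry registers it); such cells are annotated rather than silently
# asserted, and audits should treat them as ambiguous.
- act: new_taxon/suprafamilial
  ipni: not_recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: {value: recorded, table_blank: true}
- act: new_taxon/familial
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: recorded
- act: new_taxon/infrafamilial
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: recorded
- act: new_taxon/generic
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: recorded
- act: new_taxon/infrageneric
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: recorded
- act: new_taxon/specific
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: recorded
- act: new_taxon/infraspecific
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: recorded
- act: new_taxon/hybrid
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: not_applicable
- act: new_replacement_name
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: {value: recorded, table_blank: true}
- act: new_combination
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: {value: recorded, table_blank: true}
- act: tautonym
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: not_applicable
- act: typification/holotype
  ipni: recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: {value: recorded, table_blank: true}
- act: typification/lectotype
  ipni: not_recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: {value: recorded, table_blank: true}
- act: typification/neotype
  ipni: not_recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: {value: recorded, table_blank: true}
- act: typification/epitype
  ipni: not_recorded
  index_fungorum: recorded
  mycobank: recorded
  zoobank: not_applicable
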