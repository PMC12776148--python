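[
  {"canonical": "moverz_quant",
   "patterns": ["moverz quant", "m/z", "mz", "moverz", "m over z", "quant(ified)? (mz|m/z|mass)", "mass to charge( ratio)?", "quant mz"],
   "value_pattern": "\\d+(\\.\\d+)?"},
  {"canonical": "retention_time",
   "patterns": ["retention time", "ret\\.? ?time", "rt", "rt \\(min\\)", "retention time \\(min(utes)?\\)", "retention time \\(s(ec)?\\)"],
   "value_pattern": "\\d+(\\.\\d+)?( ?(s|sec|min))?"},
  {"canonical": "retention_index",
   "patterns": ["retention index", "ret\\.? ?index", "ri", "kovats index"],
   "value_pattern": "\\d+(\\.\\d+)?",
   "partners": ["retention_index_type"]},
  {"canonical": "retention_index_type",
   "patterns": ["retention index type", "ri type", "index type"]},
  {"canonical": "kegg_id",
   "patterns": ["kegg( id)?", "kegg compound( id)?", "kegg no\\.?"],
   "value_pattern": "[CDGRM]\\d{5}"},
  {"canonical": "hmdb_id",
   "patterns": ["hmdb( id)?", "hmdb accession", "hmdb no\\.?"],
   "value_pattern": "HMDB\\d{5}(\\d{2})?"},
  {"canonical": "pubchem_cid",
   "patterns": ["pubchem( id)?", "pubchem cid", "pubchem compound( id)?"],
   "value_pattern": "\\d+"},
  {"canonical": "pubchem_sid",
   "patterns": ["pubchem sid", "pubchem substance( id)?"],
   "value_pattern": "\\d+"},
  {"canonical": "inchi_key",
   "patterns": ["inchi ?key"],
   "value_pattern": "[A-Z]{14}-[A-Z]{10}-[A-Z]"},
  {"canonical": "inchi",
   "patterns": ["inchi", "inchi (code|string)"],
   "value_pattern": "InChI=.+"},
  {"canonical": "smiles",
   "patterns": ["smiles( string)?", "canonical smiles", "isomeric smiles"]},
  {"canonical": "cas_id",
   "patterns": ["cas( id| number| no\\.?| registry number)?", "casrn"],
   "value_pattern": "\\d{2,7}-\\d{2}-\\d"},
  {"canonical": "chebi_id",
   "patterns": ["chebi( id)?"],
   "value_pattern": "(CHEBI:)?\\d+"},
  {"canonical": "metlin_id",
   "patterns": ["metlin( id)?"],
   "value_pattern": "\\d+"},
  {"canonical": "lipidmaps_id",
   "patterns": ["lipid ?maps( id)?", "lm id"],
   "value_pattern": "LM[A-Z]{2}\\d{8,10}"},
  {"canonical": "chemspider_id",
   "patterns": ["chemspider( id)?"],
   "value_pattern": "\\d+"},
  {"canonical": "refmet_name",
   "patterns": ["refmet( name)?", "refmet id"]},
  {"canonical": "formula",
   "patterns": ["formula", "(molecular|chemical|elemental) formula"],
   "value_pattern": "([A-Z][a-z]?\\d*)+"},
  {"canonical": "exact_mass",
   "patterns": ["exact mass", "monoisotopic mass", "mono mass", "mass"],
   "value_pattern": "\\d+(\\.\\d+)?",
   "exclusive": ["neutral_mass"]},
  {"canonical": "neutral_mass",
   "patterns": ["neutral mass", "mass"],
   "value_pattern": "\\d+(\\.\\d+)?",
   "exclusive": ["exact_mass"]},
  {"canonical": "average_mass",
   "patterns": ["average mass", "avg\\.? mass"],
   "value_pattern": "\\d+(\\.\\d+)?"},
  {"canonical": "theoretical_mz",
   "patterns": ["theoretical (mz|m/z)", "calculated (mz|m/z)", "calc\\.? (mz|m/z)"],
   "value_pattern": "\\d+(\\.\\d+)?"},
  {"canonical": "mass_error_ppm",
   "patterns": ["mass error( ppm| \\(ppm\\))?", "ppm error", "delta ppm", "dppm"],
   "value_pattern": "-?\\d+(\\.\\d+)?"},
  {"canonical": "adduct",
   "patterns": ["adduct( type| ion)?", "ion adduct"]},
  {"canonical": "adduct_mz",
   "patterns": ["adduct (mz|m/z)"],
   "value_pattern": "\\d+(\\.\\d+)?"},
  {"canonical": "isotope",
   "patterns": ["isotope( label)?", "isotopologue"]},
  {"canonical": "charge",
   "patterns": ["charge( state)?"],
   "value_pattern": "[+-]?\\d+"},
  {"canonical": "polarity",
   "patterns": ["polarity", "ion polarity", "esi (mode|polarity)"],
   "value_pattern": "(?i:positive|negative|pos|neg)|\\+|-"},
  {"canonical": "ionization",
   "patterns": ["ioni[sz]ation( mode)?", "ion mode"]},
  {"canonical": "ms_level",
   "patterns": ["ms level", "msn level"],
   "value_pattern": "(?i:MS)?[1-9]"},
  {"canonical": "collision_energy",
   "patterns": ["collision energy( \\(?e?v\\)?)?", "ce"],
   "value_pattern": "\\d+(\\.\\d+)?( ?(?i:eV|V))?"},
  {"canonical": "precursor_mz",
   "patterns": ["precursor (mz|m/z|ion)", "parent (mz|m/z|ion)"],
   "value_pattern": "\\d+(\\.\\d+)?"},
  {"canonical": "product_mz",
   "patterns": ["product (mz|m/z|ion)", "fragment (mz|m/z|ion)"],
   "value_pattern": "\\d+(\\.\\d+)?"},
  {"canonical": "quant_ion",
   "patterns": ["quant(ification)? ion", "quantifier( ion)?"]},
  {"canonical": "qualifier_ion",
   "patterns": ["qualifier( ion)?", "confirm(ing)? ion"]},
  {"canonical": "peak_area",
   "patterns": ["peak area", "area"],
   "value_pattern": "\\d+(\\.\\d+)?([eE][+-]?\\d+)?"},
  {"canonical": "peak_height",
   "patterns": ["peak height", "height"],
   "value_pattern": "\\d+(\\.\\d+)?([eE][+-]?\\d+)?"},
  {"canonical": "signal_to_noise",
   "patterns": ["signal to noise( ratio)?", "s/n( ratio)?", "sn ratio"],
   "value_pattern": "\\d+(\\.\\d+)?"},
  {"canonical": "detection_limit",
   "patterns": ["detection limit", "lod", "limit of detection"]},
  {"canonical": "quantification_limit",
   "patterns": ["quantification limit", "loq", "limit of quantification"]},
  {"canonical": "annotation_level",
   "patterns": ["annotation level", "msi level", "identification level", "id level"],
   "value_pattern": "[1-4][a-b]?"},
  {"canonical": "confidence_score",
   "patterns": ["confidence( score)?", "score", "match score"],
   "value_pattern": "\\d+(\\.\\d+)?%?"},
  {"canonical": "spectrum_id",
   "patterns": ["spectrum( id| index)?", "scan( number| id)?"]},
  {"canonical": "library_match",
   "patterns": ["library (match|hit)", "spectral match", "library"]},
  {"canonical": "compound_class",
   "patterns": ["compound class", "class", "lipid class", "chemical class"]},
  {"canonical": "other_id",
   "patterns": ["other ids?", "alt(ernate)? ids?", "additional ids?"],
   "partners": ["other_id_type"]},
  {"canonical": "other_id_type",
   "patterns": ["other ids? type", "alt(ernate)? id type"]},
  {"canonical": "lab_id",
   "patterns": ["lab(oratory)? id", "internal id", "local id", "in house id"]},
  {"canonical": "sample_id",
   "patterns": ["sample( id| name| identifier)?", "specimen( id)?"]},
  {"canonical": "subject_id",
   "patterns": ["subject( id)?", "patient( id)?"]},
  {"canonical": "metabolite_id",
   "patterns": ["metabolite id", "compound id", "met\\.? id"]},
  {"canonical": "metabolite_synonyms",
   "patterns": ["(metabolite )?synonyms?", "alt(ernate)? names?", "other names?"]},
  {"canonical": "quantified_compound",
   "patterns": ["quantified (compound|metabolite)"]},
  {"canonical": "standard_concentration",
   "patterns": ["standard concentration", "std\\.? conc(entration)?\\.?"],
   "value_pattern": "\\d+(\\.\\d+)?"},
  {"canonical": "internal_standard",
   "patterns": ["internal standard", "istd", "is"]},
  {"canonical": "comments",
   "patterns": ["comments?", "notes?", "remarks?"]}
]
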