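# Compound-name stripping rules, applied in file order (case-insensitive).
#
# Format: one rule per line, "<op>\t<regex>".
#   split   the regex must match the whole name; every non-empty capture
#           group becomes a separate constituent (applied recursively).
#   remove  every match of the regex is deleted from the name.
# Lines starting with "#" and blank lines are ignored.

# -- multi-compound constructions ------------------------------------------
split	^(.*?)\s*/\s*(.+)$
split	^(.*\S)\s+solution\s+of\s+(\S.*)$
split	^solution\s+of\s+(\S.*)$
split	^(\S.*\S)\s+dissolved\s+in\s+(\S.*)$

# -- leading quantities -----------------------------------------------------
remove	^\s*\d+(?:\.\d+)?\s*(?:ml|l|ul|g|mg|kg|mol|mmol|umol|drops?|portions?|equivalents?|equiv\.?|eq\.?)\s+(?:of\s+)?

# -- concentration qualifiers ----------------------------------------------
remove	\b\d+(?:\.\d+)?\s*(?:wt\s*%|%|m|n)(?=[\s,.)]|$)\.?
remove	\bsaturated\b
remove	\bconcentrated\b
remove	\bconc\.?\s
remove	\baqueous\b
remove	\baq\.?\s
remove	\banhydrous\b
remove	\bdiluted?\b

# -- composition ratios -----------------------------------------------------
remove	\(\s*\d+(?:\.\d+)?(?:\s*[:/]\s*\d+(?:\.\d+)?)+\s*\)
remove	\b\d+(?:\.\d+)?(?:\s*[:/]\s*\d+(?:\.\d+)?)+(?=\s|$)

# -- physical state ---------------------------------------------------------
remove	\bsolid\b
remove	\bgaseous\b
remove	\(\s*s\s*\)
remove	\(\s*l\s*\)
remove	\(\s*g\s*\)
remove	\(\s*aq\.?\s*\)

# -- temperature qualifiers -------------------------------------------------
remove	\bice[- ]cold\b
remove	\bcold\b
remove	\bhot\b
remove	\bwarm\b
remove	\bchilled\b

# -- leftover function words ------------------------------------------------
remove	^\s*(?:a|an|the)\s+
remove	^\s*of\s+
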