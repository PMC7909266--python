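# Provenance notes for the packaged picnic-scene content-unit lexicon

The lexicon reproduces the published 64-concept dictionary for the WAB-R
"Picnic Scene" picture-description task (the set of concepts mentioned by at
least three of 31 healthy controls), with the referent sub-units used by the
unique-referent coding scheme. Editorial corrections and storage conventions:

- CU #30 is printed as "Nasket" in the source table; this is an evident typo
  for "basket" and the fixture stores "basket".
- Variants printed with a disambiguating parenthetical, e.g. "caught (a
  fish)", are stored as the head phrase ("caught"); the parenthetical is
  context, not a required string. Exception: CU #31 "(Man's) glasses" is
  stored as the full phrase "man's glasses" because the bare head "glasses"
  already belongs to CU #24 and variant phrases must be unique across the
  lexicon.
- Plural markers printed in parentheses ("Sandcastle(s)", "Sandwich(es)") are
  stored as the singular; the matcher's inflection table covers the plural.
- CU #44 ("grass"/"yard"/...) and CU #54 ("bloom") carry a "No Pattern" or
  single-referent entry in the referent column and are never subdivided under
  the unique-referent scheme; the referent column on their parent rows is
  informational only.
- Sub-unit control counts are printed only for 43a (18) and 43b (15); other
  sub-rows have no count and inherit validation from their parent.
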