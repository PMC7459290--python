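# The sectioned pedigree-file dialect

Tab-delimited UTF-8 text with four sections in fixed order: **header**,
**pedigree + phenotypes**, and the optional genotypic part (**linkage-group
maps**, **observed marker alleles**) and **IBD probabilities**.  Blank lines
are ignored anywhere; lines starting with `#` are comments.  Sections are
introduced by reserved keyword lines.  The original visualization programs
document this layout only by example, so the keyword grammar below is this
package's own, self-consistent formalization; byte-exact compatibility with
any specific external program is not claimed.

## Header

One `KEY<TAB>value` line per element.  Five elements are mandatory,
`NALLELES` is required only when IBD blocks are present.

| keyword         | meaning                                          |
|-----------------|--------------------------------------------------|
| `POPULATION`    | population name (token without whitespace)       |
| `PLOIDY`        | positive integer (rice: 2)                       |
| `UNKNOWN`       | code for missing data / unknown parents          |
| `POSSIBLENULL`  | code for possible null alleles                   |
| `CONFIRMEDNULL` | code for confirmed null alleles                  |
| `NALLELES`      | total founder alleles = ploidy x founders        |

The three codes must be pairwise distinct.

## Pedigree section

Starts with a `PEDIGREE` line, followed by one column-header row and one row
per individual.  The first three columns are `Name`, `Mother`, `Father`;
names are tokens without whitespace and the unknown-code in a parent column
means "no parent".  A **founder** has both parents unknown.  A record with
exactly one known parent is legal (warning): the unknown gamete is treated
internally as a *phantom founder*, and `NALLELES` accounting generalizes to
`ploidy x (founders + phantom founders)`.

Phenotype columns follow.  Column headers may be annotated `name:Q[:units]`
(quantitative) or `name:C[:units]` (categorical); a bare `name` is inferred
quantitative iff every non-missing cell parses as a number.  Missing cells
carry the unknown-code.  The writer always emits annotated headers and
formats numbers with the shortest representation that round-trips the value
exactly (so `parse(write(d))` equals `d` field-for-field, including IBD
probabilities).

## Genotypic part

* `MAP <group>` opens a linkage-group map; each following row is
  `<locus><TAB><position_cM>` with non-decreasing positions.  All maps come
  before allele data; locus names are unique across groups.
* `LOCUS <locus>` opens an observed-alleles block; each row is
  `<individual><TAB><allele_1>...<allele_ploidy>` (exactly `PLOIDY` allele
  codes; the missing/null codes are legal allele codes).

## IBD section

`IBD <group> <position_cM>` opens one block per evaluated position; each row
is `<individual><TAB><p_1>...<p_NALLELES>`.  Entry *k* is the expected number
of the individual's gene copies descending from founder allele *k*, so every
entry lies in [0, 1] and each row sums to the ploidy (tolerance 1e-6).
Founder-allele order is pedigree-file order of the founders, then slot
1..ploidy within each founder (phantom founders last).  Rows are normalized
per individual (sum = ploidy), not per gene copy: founder rows are then unit
indicators on their own slots.  If the file has no maps, a block may use the
pseudo-group `pedigree` at position 0.

## Golden example

```
POPULATION	DEMO
PLOIDY	2
UNKNOWN	-
POSSIBLENULL	?
CONFIRMEDNULL	!
NALLELES	4

PEDIGREE
Name	Mother	Father	yield:Q:mt/ha	pericarp_color:C
A	-	-	6	white
B	-	-	4	red
F1	A	B	5.5	-

MAP	LG1
RM001	0
RM005	25

LOCUS	RM001
A	100	102
B	104	106
F1	100	104

IBD	LG1	0
A	1	1	0	0
B	0	0	1	1
F1	0.5	0.5	0.5	0.5
```
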