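"""Packaged cohort frequency table of the 59 panel variants confirmed on the
second sequencing platform, with het/hom carrier counts across the four
lesion groups (30 normal / 21 adenoma / 33 advanced adenoma / 56 CRC).

Loci are hg19 positions without chromosome prefixes; the chromosome is
resolved from the gene (APC, MSH3, DHFR -> chr5; MSH6 -> chr2).
"""
from __future__ import annotations

import io
import warnings

import pandas as pd

from .model import GENE_CHROMOSOMES, Tissue, parse_functional_class
from .zygosity import FrequencyTable, GROUP_ORDER

GROUP_SIZES = {
    Tissue.NORMAL: 30,
    Tissue.ADENOMA: 21,
    Tissue.ADVANCED_ADENOMA: 33,
    Tissue.CRC: 56,
}

# position ref alt gene type novel  N-het N-hom A-het A-hom AA-het AA-hom C-het C-hom
_CONFIRMED_VARIANTS_TSV = """\
position	ref	alt	gene	type	novel	het_normal	hom_normal	het_adenoma	hom_adenoma	het_advanced_adenoma	hom_advanced_adenoma	het_crc	hom_crc
112043384	T	G	APC	Intronic	0	6	0	3	0	7	1	12	0
112103015	C	A	APC	Stopgain	0	0	0	0	0	0	0	0	0
112116592	C	T	APC	Stopgain	0	0	0	0	0	0	0	2	0
112128191	C	T	APC	Stopgain	0	0	0	1	0	2	0	2	0
112136947	A	T	APC	Intronic	0	3	0	2	0	3	0	3	0
112151261	C	T	APC	Stopgain	0	0	0	0	0	1	0	1	0
112154942	C	T	APC	Stopgain	0	0	0	1	0	1	0	1	0
112154980	T	A	APC	Stopgain	1	0	0	1	0	0	0	0	0
112157658	G	T	APC	Stopgain	1	0	0	1	0	0	0	0	0
112162854	T	C	APC	Synonymous SNV	0	11	1	7	2	14	2	17	6
112164561	G	A	APC	Synonymous SNV	0	16	5	14	6	20	7	27	16
112173553	T	G	APC	Synonymous SNV	0	1	0	1	0	0	0	0	0
112173899	C	T	APC	Non-synonymous SNV	0	1	0	1	0	2	0	3	0
112174096	C	A	APC	Stopgain	0	0	0	0	0	1	0	0	0
112174763	A	T	APC	Stopgain	1	0	0	0	0	0	0	1	0
112175023	A	G	APC	Synonymous SNV	0	3	0	2	0	4	0	3	0
112175030	G	A	APC	Non-synonymous SNV	0	1	0	0	0	0	0	2	0
112175069	C	T	APC	Stopgain	0	0	0	1	0	0	0	2	0
112175207	G	T	APC	Stopgain	0	0	0	0	0	0	0	2	0
112175399	A	T	APC	Stopgain	0	0	0	0	0	2	0	1	0
112175576	C	T	APC	Stopgain	0	0	0	0	0	3	0	0	0
112175639	C	T	APC	Stopgain	0	0	0	2	0	4	0	2	0
112175770	G	A	APC	Synonymous SNV	0	17	5	13	7	20	8	26	14
112176325	G	A	APC	Synonymous SNV	0	19	4	14	6	21	6	26	17
112176541	C	G	APC	Synonymous SNV	0	1	0	1	0	0	0	2	0
112176559	T	G	APC	Synonymous SNV	0	18	4	13	7	19	8	26	17
112176756	T	A	APC	Non-synonymous SNV	0	3	26	4	17	8	24	4	50
112176918	G	C	APC	Non-synonymous SNV	1	0	0	0	0	1	0	0	0
112177171	G	A	APC	Synonymous SNV	0	16	5	14	6	21	7	31	15
112178492	C	T	APC	Synonymous SNV	0	0	0	0	0	1	0	1	0
112178795	G	A	APC	Non-synonymous SNV	0	1	0	0	0	0	0	2	0
112178995	A	G	APC	Synonymous SNV	0	7	0	3	0	6	0	6	2
112179909	C	A	APC	Intronic	0	9	1	9	1	12	0	20	3
79950497	C	T	DHFR, MSH3	Intronic	0	6	4	6	2	3	2	14	5
79950508	C	T	DHFR, MSH3	Intronic	0	4	0	1	0	3	0	5	0
79950512	A	G	DHFR, MSH3	Intronic	0	5	14	1	8	3	8	13	26
79960955	G	A	MSH3	Intronic	0	11	5	10	4	16	1	24	7
79966029	G	A	MSH3	Synonymous SNV	0	6	1	11	0	5	2	16	0
79966197	G	A	MSH3	Intronic	0	11	5	11	4	19	1	26	5
79968496	C	T	MSH3	Intronic	0	5	3	3	3	11	1	13	3
80024685	C	A	MSH3	Non-synonymous SNV	0	0	0	2	0	0	0	0	0
80024738	A	G	MSH3	Non-synonymous SNV	0	0	0	0	0	2	0	0	0
80024783	G	A	MSH3	Non-synonymous SNV	0	1	0	0	0	5	0	2	0
80083459	G	A	MSH3	Synonymous SNV	0	1	0	0	0	2	0	1	0
80149981	A	G	MSH3	Non-synonymous SNV	0	2	27	4	16	7	23	5	48
80160610	T	A	MSH3	Intronic	0	5	2	4	0	4	1	12	1
80168937	G	A	MSH3	Non-synonymous SNV	0	11	15	10	8	19	10	22	30
48022981	G	T	MSH6	Intronic	0	10	3	12	1	11	1	23	4
48023115	T	C	MSH6	Synonymous SNV	0	9	1	5	1	7	1	14	1
48026286	C	T	MSH6	Synonymous SNV	0	4	0	2	0	4	0	7	0
48027375	T	C	MSH6	Synonymous SNV	0	4	0	2	0	7	0	5	1
48030692	T	A	MSH6	Synonymous SNV	0	0	0	0	0	1	0	0	0
48030838	A	T	MSH6	Intronic	0	10	2	12	0	8	1	17	2
48032908	A	G	MSH6	Intronic	1	1	0	1	0	0	0	2	0
48032937	T	C	MSH6	Intronic	0	4	25	4	17	9	21	12	40
48033514	T	C	MSH6	Intronic	0	0	0	2	0	2	0	1	0
48033545	A	C	MSH6	Intronic	1	0	0	0	0	0	0	1	0
48033551	C	G	MSH6	Intronic	0	4	20	3	11	8	9	13	34
48033700	G	A	MSH6	Non-synonymous SNV	0	1	0	2	0	0	0	2	0
"""


def make_table2_fixture() -> FrequencyTable:
    """Build the packaged confirmed-variant frequency table (59 rows).

    One row (APC 112103015, a stopgain) has zero carriers in every group but
    is retained as published; a warning flags it.
    """
    df = pd.read_csv(io.StringIO(_CONFIRMED_VARIANTS_TSV), sep="\t")
    df.insert(0, "chromosome", df["gene"].map(GENE_CHROMOSOMES))
    df = df.rename(columns={"alt": "alt"})
    df["functional_class"] = [parse_functional_class(t).value for t in df.pop("type")]
    df["novel"] = df["novel"].astype(bool)
    cols = ["chromosome", "position", "ref", "alt", "gene", "functional_class", "novel"]
    cols += [f"{z}_{g.value}" for g in GROUP_ORDER for z in ("het", "hom")]
    return FrequencyTable(df=df[cols], group_sizes=dict(GROUP_SIZES))
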