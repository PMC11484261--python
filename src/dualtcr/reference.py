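"""Published per-sample pairing counts for a Kawasaki-disease IVIG cohort.

These are the published summary counts for the 15-sample scRNA+scTCR-seq
cohort deposited as GEO series GSE168732: six Kawasaki-disease patients
sampled before and after intravenous immunoglobulin (IVIG) treatment plus
three healthy controls.  For each sample the table records the total cell
count, the paired-TCR cell count (cells with at least one productive α and
one productive β chain), and the per-class counts of the five pairing types,
together with the percentages as printed in the original report.

They serve two purposes: a realistic fixture for the summary/statistics
layers, and the calibration target the synthetic cohort preset emulates.
"""

from __future__ import annotations

import io

import pandas as pd

from .pairing import SampleSummary

# sample, patient, group, GSM accession, total cells, paired, single, dual
# subtype counts, then the percentages as printed in the original report
# (printed values occasionally truncate rather than round; they stay within
# ±0.01 of 100*count/paired).
_COHORT_TSV = """\
sample_id	patient_id	group	gsm	total_cells	n_paired	n_single	n_dual_a_b1b2	n_dual_b_a1a2	n_dual_a1a2b1b2	n_dual_total	n_others	printed_single	printed_dual_total	printed_a_b1b2	printed_b_a1a2	printed_a1a2b1b2	printed_others
KD1_pre	KD1	pre_ivig	GSM5160417	2354	1217	1161	41	13	1	56	1	95.40	4.60	3.37	1.07	0.08	0.08
KD2_pre	KD2	pre_ivig	GSM5160420	3283	2593	2290	75	180	41	303	7	88.31	11.68	2.89	6.94	1.58	0.27
KD3_pre	KD3	pre_ivig	GSM5160422	3539	3076	2612	104	288	49	464	23	84.92	15.08	3.38	9.36	1.59	0.75
KD4_pre	KD4	pre_ivig	GSM5160424	3284	2302	2080	74	125	17	222	6	90.36	9.64	3.21	5.43	0.74	0.26
KD5_pre	KD5	pre_ivig	GSM5160427	3276	2837	2458	76	270	33	379	0	86.64	13.35	2.68	9.52	1.16	0.00
KD6_pre	KD6	pre_ivig	GSM5160430	1707	1424	1263	32	122	7	161	0	88.69	11.31	2.25	8.57	0.49	0.00
KD1_post	KD1	post_ivig	GSM5160419	3322	2911	2504	82	269	40	407	16	86.02	13.98	2.82	9.24	1.37	0.55
KD2_post	KD2	post_ivig	GSM5160421	6352	5647	4576	323	547	131	1071	70	81.03	18.97	5.72	9.69	2.32	1.24
KD3_post	KD3	post_ivig	GSM5160423	4835	4398	3655	130	473	103	743	37	83.11	16.89	2.96	10.75	2.34	0.84
KD4_post	KD4	post_ivig	GSM5160425	3187	2600	2216	194	110	33	384	47	85.23	14.77	7.46	4.23	1.27	1.81
KD5_post	KD5	post_ivig	GSM5160428	4235	2916	2552	123	190	51	364	0	87.52	12.48	4.22	6.52	1.75	0.00
KD6_post	KD6	post_ivig	GSM5160431	3163	1924	1651	74	178	21	273	0	85.81	14.19	3.85	9.25	1.09	0.00
NC1	NC1	control	GSM5160432	4087	3350	2944	139	214	34	406	19	87.88	12.12	4.15	6.39	1.01	0.57
NC2	NC2	control	GSM5160434	3016	2389	2102	78	173	24	287	12	87.99	12.01	3.26	7.24	1.00	0.50
NC3	NC3	control	GSM5160435	3285	2844	2493	79	236	30	351	6	87.66	12.34	2.78	8.30	1.05	0.21
"""

_NUMERIC = [
    "total_cells",
    "n_paired",
    "n_single",
    "n_dual_a_b1b2",
    "n_dual_b_a1a2",
    "n_dual_a1a2b1b2",
    "n_dual_total",
    "n_others",
    "printed_single",
    "printed_dual_total",
    "printed_a_b1b2",
    "printed_b_a1a2",
    "printed_a1a2b1b2",
    "printed_others",
]


def cohort_counts() -> pd.DataFrame:
    """The published cohort table, one row per sample."""
    df = pd.read_csv(io.StringIO(_COHORT_TSV), sep="\t")
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col])
    return df


def cohort_summaries() -> list[SampleSummary]:
    """The published counts as :class:`SampleSummary` objects (validated)."""
    out = []
    for row in cohort_counts().itertuples(index=False):
        s = SampleSummary(
            sample_id=row.sample_id,
            group=row.group,
            n_paired=int(row.n_paired),
            n_single=int(row.n_single),
            n_dual_a_b1b2=int(row.n_dual_a_b1b2),
            n_dual_b_a1a2=int(row.n_dual_b_a1a2),
            n_dual_a1a2b1b2=int(row.n_dual_a1a2b1b2),
            n_others=int(row.n_others),
        )
        s.validate()
        out.append(s)
    return out


def cohort_manifest() -> pd.DataFrame:
    """Sample manifest (sample_id, patient_id, group) for the cohort."""
    return cohort_counts()[["sample_id", "patient_id", "group"]].copy()
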