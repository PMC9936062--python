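# Pathogenic CNVs reported in a published AVSD whole-exome case cohort
# (150 cases / 100 controls); coordinates are hg19, half-open arithmetic
# (region size = END - START). Used as a worked-example input.
SAMPLE	CHROM	START	END	CYTOBAND	TYPE
191252	chr1	146584283	147806803	1q21.1-q21.2	DEL
223503	chr2	110855124	110962791	2q13	DEL
224312	chr2	110855124	110962647	2q13	DEL
61	chr2	110827494	110962635	2q13	DEL
183217	chr8	8098153	10588092	8p23.1	DEL
W101	chr16	21391473	21830024	16p12.2	DEL
172905	chr16	21608536	21907102	16p12.2	DEL
207063	chr21	26946247	48084365	21q22.11-21q22.3	DUP
210973	chr21	26946247	48084365	21q22.11-21q22.3	DUP
209182	chr21	26946247	45837963	21q22.11-21q22.3	DUP
221308	chr21	30250542	48084365	21q22.11-21q22.3	DUP
241802	chr21	30250542	48084365	21q22.11-21q22.3	DUP
201013	chr21	30251994	48084365	21q22.11-21q22.3	DUP
225462	chr21	30251994	48084365	21q22.11-21q22.3	DUP
264282	chr21	30251994	40551975	21q22.11-21q22.2	DUP
208738	chr21	30257471	48084365	21q22.11-21q22.3	DUP
204113	chr21	30303475	40695048	21q22.11-21q22.2	DUP
205219	chr21	34117827	48084365	21q22.11-21q22.3	DUP
172905	chr21	37408332	48084365	21q22.13-21q22.3	DUP
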