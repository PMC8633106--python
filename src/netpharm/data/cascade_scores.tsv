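chain	score
ADCY1--cAMP--PRKACA--RHOA	0.962
ADCY1--cAMP--PRKACA--GRIA1	0.939
ADCY1--cAMP--PRKACA--GRIN2A	0.916
DRD1--GNAQ--PLCB1--DAG--PRKCA--FOS	0.867
ADCY1--cAMP--PRKACA--GRIA1--GSK3A	0.801
DRD5--GNAQ--PLCB1--DAG--PRKCA--FOS	0.793
ADCY1--cAMP--PRKACA--CREB3--BDNF	0.790
ADCY1--cAMP--PRKACA--CREB3--FOS	0.754
ADCYAP1R1--GNAS--ADCY1--cAMP--PRKACA--RHOA	0.735
ADCYAP1R1--GNAS--ADCY1--cAMP--PRKACA--GRIA1	0.720
ADCY1--cAMP--PRKACA--MAPK14--ATF2	0.710
ADCY1--cAMP--RAPGEF3--MAPK8--JUND	0.710
ADCYAP1R1--GNAS--ADCY1--cAMP--PRKACA--GRIN2A	0.705
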