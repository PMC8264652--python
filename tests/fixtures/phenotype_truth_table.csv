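CD20_aggregate,CXCL13,CD4,CD21_network,CD23_network,BCL6,phenotype
0,0,0,0,0,0,UNCLASSIFIED
0,0,0,0,0,1,UNCLASSIFIED
0,0,0,0,1,0,UNCLASSIFIED
0,0,0,0,1,1,UNCLASSIFIED
0,0,0,1,0,0,UNCLASSIFIED
0,0,0,1,0,1,UNCLASSIFIED
0,0,0,1,1,0,UNCLASSIFIED
0,0,0,1,1,1,UNCLASSIFIED
0,0,1,0,0,0,UNCLASSIFIED
0,0,1,0,0,1,UNCLASSIFIED
0,0,1,0,1,0,UNCLASSIFIED
0,0,1,0,1,1,UNCLASSIFIED
0,0,1,1,0,0,UNCLASSIFIED
0,0,1,1,0,1,UNCLASSIFIED
0,0,1,1,1,0,UNCLASSIFIED
0,0,1,1,1,1,UNCLASSIFIED
0,1,0,0,0,0,UNCLASSIFIED
0,1,0,0,0,1,UNCLASSIFIED
0,1,0,0,1,0,UNCLASSIFIED
0,1,0,0,1,1,UNCLASSIFIED
0,1,0,1,0,0,UNCLASSIFIED
0,1,0,1,0,1,UNCLASSIFIED
0,1,0,1,1,0,UNCLASSIFIED
0,1,0,1,1,1,UNCLASSIFIED
0,1,1,0,0,0,UNCLASSIFIED
0,1,1,0,0,1,UNCLASSIFIED
0,1,1,0,1,0,UNCLASSIFIED
0,1,1,0,1,1,UNCLASSIFIED
0,1,1,1,0,0,UNCLASSIFIED
0,1,1,1,0,1,UNCLASSIFIED
0,1,1,1,1,0,UNCLASSIFIED
0,1,1,1,1,1,UNCLASSIFIED
1,0,0,0,0,0,UNCLASSIFIED
1,0,0,0,0,1,UNCLASSIFIED
1,0,0,0,1,0,UNCLASSIFIED
1,0,0,0,1,1,UNCLASSIFIED
1,0,0,1,0,0,UNCLASSIFIED
1,0,0,1,0,1,UNCLASSIFIED
1,0,0,1,1,0,UNCLASSIFIED
1,0,0,1,1,1,UNCLASSIFIED
1,0,1,0,0,0,UNCLASSIFIED
1,0,1,0,0,1,UNCLASSIFIED
1,0,1,0,1,0,UNCLASSIFIED
1,0,1,0,1,1,UNCLASSIFIED
1,0,1,1,0,0,PRIMARY_FOLLICULAR
1,0,1,1,0,1,UNCLASSIFIED
1,0,1,1,1,0,SECONDARY_FOLLICULAR_BCL6NEG
1,0,1,1,1,1,SECONDARY_FOLLICULAR_BCL6POS
1,1,0,0,0,0,EARLY
1,1,0,0,0,1,UNCLASSIFIED
1,1,0,0,1,0,UNCLASSIFIED
1,1,0,0,1,1,UNCLASSIFIED
1,1,0,1,0,0,UNCLASSIFIED
1,1,0,1,0,1,UNCLASSIFIED
1,1,0,1,1,0,UNCLASSIFIED
1,1,0,1,1,1,UNCLASSIFIED
1,1,1,0,0,0,EARLY
1,1,1,0,0,1,UNCLASSIFIED
1,1,1,0,1,0,UNCLASSIFIED
1,1,1,0,1,1,UNCLASSIFIED
1,1,1,1,0,0,PRIMARY_FOLLICULAR
1,1,1,1,0,1,UNCLASSIFIED
1,1,1,1,1,0,SECONDARY_FOLLICULAR_BCL6NEG
1,1,1,1,1,1,SECONDARY_FOLLICULAR_BCL6POS
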