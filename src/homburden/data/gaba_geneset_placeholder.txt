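# Placeholder 120-gene 'GABA system' set (synthetic stand-in).
# The original curated list is a user-supplied input; this fixture
# combines well-known GABAergic genes with placeholder symbols so
# the pipeline can run end-to-end without external databases.
GAD1
GAD2
ABAT
ALDH5A1
GPHN
ADCY3
ADCY8
HSPA8
CNTNAP4
HAP1
GABBR1
GABBR2
SLC6A1
SLC6A11
SLC6A12
SLC6A13
SLC32A1
DBI
PLCL1
TRAK2
NSF
USP14
ARHGEF9
GABARAP
GABARAPL1
GABARAPL2
GABRA1
GABRA2
GABRA3
GABRA4
GABRA5
GABRA6
GABRB1
GABRB2
GABRB3
GABRG1
GABRG2
GABRG3
GABRD
GABRE
GABRP
GABRQ
GABRR1
GABRR2
GABRR3
GABASET_PLACEHOLDER_001
GABASET_PLACEHOLDER_002
GABASET_PLACEHOLDER_003
GABASET_PLACEHOLDER_004
GABASET_PLACEHOLDER_005
GABASET_PLACEHOLDER_006
GABASET_PLACEHOLDER_007
GABASET_PLACEHOLDER_008
GABASET_PLACEHOLDER_009
GABASET_PLACEHOLDER_010
GABASET_PLACEHOLDER_011
GABASET_PLACEHOLDER_012
GABASET_PLACEHOLDER_013
GABASET_PLACEHOLDER_014
GABASET_PLACEHOLDER_015
GABASET_PLACEHOLDER_016
GABASET_PLACEHOLDER_017
GABASET_PLACEHOLDER_018
GABASET_PLACEHOLDER_019
GABASET_PLACEHOLDER_020
GABASET_PLACEHOLDER_021
GABASET_PLACEHOLDER_022
GABASET_PLACEHOLDER_023
GABASET_PLACEHOLDER_024
GABASET_PLACEHOLDER_025
GABASET_PLACEHOLDER_026
GABASET_PLACEHOLDER_027
GABASET_PLACEHOLDER_028
GABASET_PLACEHOLDER_029
GABASET_PLACEHOLDER_030
GABASET_PLACEHOLDER_031
GABASET_PLACEHOLDER_032
GABASET_PLACEHOLDER_033
GABASET_PLACEHOLDER_034
GABASET_PLACEHOLDER_035
GABASET_PLACEHOLDER_036
GABASET_PLACEHOLDER_037
GABASET_PLACEHOLDER_038
GABASET_PLACEHOLDER_039
GABASET_PLACEHOLDER_040
GABASET_PLACEHOLDER_041
GABASET_PLACEHOLDER_042
GABASET_PLACEHOLDER_043
GABASET_PLACEHOLDER_044
GABASET_PLACEHOLDER_045
GABASET_PLACEHOLDER_046
GABASET_PLACEHOLDER_047
GABASET_PLACEHOLDER_048
GABASET_PLACEHOLDER_049
GABASET_PLACEHOLDER_050
GABASET_PLACEHOLDER_051
GABASET_PLACEHOLDER_052
GABASET_PLACEHOLDER_053
GABASET_PLACEHOLDER_054
GABASET_PLACEHOLDER_055
GABASET_PLACEHOLDER_056
GABASET_PLACEHOLDER_057
GABASET_PLACEHOLDER_058
GABASET_PLACEHOLDER_059
GABASET_PLACEHOLDER_060
GABASET_PLACEHOLDER_061
GABASET_PLACEHOLDER_062
GABASET_PLACEHOLDER_063
GABASET_PLACEHOLDER_064
GABASET_PLACEHOLDER_065
GABASET_PLACEHOLDER_066
GABASET_PLACEHOLDER_067
GABASET_PLACEHOLDER_068
GABASET_PLACEHOLDER_069
GABASET_PLACEHOLDER_070
GABASET_PLACEHOLDER_071
GABASET_PLACEHOLDER_072
GABASET_PLACEHOLDER_073
GABASET_PLACEHOLDER_074
GABASET_PLACEHOLDER_075
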