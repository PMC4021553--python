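H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
R LIT:0807099b PMID:7108955
A Kyte, J. and Doolittle, R.F.
T A simple method for displaying the hydropathic character of a protein
J J. Mol. Biol. 157, 105-132 (1982)
C GIAG010101    0.994  JURD980101    0.997  OLSK800101    0.902
  ROSG850102    0.905  WOLR790101    0.904
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.800  -4.500  -3.500  -3.500   2.500  -3.500  -3.500  -0.400  -3.200   4.500
    3.800  -3.900   1.900   2.800  -1.600  -0.800  -0.700  -0.900  -1.300   4.200
//
H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
R LIT:0692004 PMID:6167991
A Hopp, T.P. and Woods, K.R.
T Prediction of protein antigenic determinants from amino acid sequences
J Proc. Natl. Acad. Sci. USA 78, 3824-3828 (1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.500   3.000   0.200   3.000  -1.000   0.200   3.000   0.000  -0.500  -1.800
   -1.800   3.000  -1.300  -2.500   0.000   0.300  -0.400  -3.400  -2.300  -1.500
//
H FAKE000001
D Incomplete test entry with missing values
R
A Nobody
T Placeholder entry used to exercise NA handling
J Unpublished
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.000      NA   0.500   0.100   0.200   0.300   0.400   0.500   0.600   0.700
    0.800   0.900   1.100   1.200   1.300   1.400   1.500   1.600   1.700   1.800
//
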