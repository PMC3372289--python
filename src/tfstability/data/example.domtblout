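#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
read_0001            -            210 HTH_1                -             61   1.1e-12   46.0   0.1   1   1   1.1e-12   2.1e-12   45.3   0.1     5    58    12    64    10    66 0.95 translated read
read_0002            -            480 Aldedh               -            462   1.2e-25  181.0   2.2   1   1   1.7e-25   3.4e-25  180.2   2.2    10   460     5   455     3   458 0.97 translated read
read_0003            -            150 LacI                 -             46   4.1e-04   21.0   1.9   1   1   4.1e-04   8.0e-04   20.1   1.9     1    12    33    44    30    46 0.88 translated read
read_0004            -            190 Response_reg         -            112   2.8e-09   62.8   0.8   1   1   2.8e-09   5.5e-09   62.0   0.8     3   110    20   128    18   130 0.94 translated read
read_0005            -            160 TetR_N               -             47   6.0e-07   39.0   0.0   1   1   6.0e-07   1.2e-06   38.4   0.0     2    46     8    52     6    54 0.96 translated read
read_0006            -            175 MarR                 -             58   5.0e-10   52.3   1.0   1   1   5.0e-10   9.9e-10   51.7   1.0     1    57    40    96    38    98 0.95 translated read
read_0007            -            205 HTH_1                -             61   5.0e-03   16.2   0.3   1   1   5.0e-03   1.0e-02   15.8   0.3     5    55    60   110    58   112 0.81 decoy fails E-value
read_0008            -            320 Aldedh               -            462   5.0e-09   70.6   0.5   1   1   5.0e-09   1.0e-08   70.0   0.5   100   150    10    60     8    62 0.90 decoy fails coverage
read_0009            -            140 LacI                 -             46   1.0e-06   18.6   9.0   1   1   1.0e-06   2.0e-06   18.0   9.0     1    40    70   109    68   111 0.85 decoy fails bias
read_0010            -            130 Response_reg         -            112   2.5e-01   12.4   0.2   1   1   2.5e-01   5.0e-01   12.0   0.2    50    60    15    25    13    27 0.70 decoy fails E-value and coverage
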