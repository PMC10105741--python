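CTRL1_c001
CTRL1_c002
CTRL1_c003
CTRL1_c004
CTRL1_c005
CTRL1_c006
CTRL1_c007
CTRL1_c008
CTRL1_c009
CTRL1_c010
CTRL1_c011
CTRL1_c012
CTRL1_c013
CTRL1_c014
CTRL1_c015
CTRL2_c001
CTRL2_c002
CTRL2_c003
CTRL2_c004
CTRL2_c005
CTRL2_c006
CTRL2_c007
CTRL2_c008
CTRL2_c009
CTRL2_c010
CTRL2_c011
CTRL2_c012
CTRL2_c013
CTRL2_c014
CTRL2_c015
CASE1_c001
CASE1_c002
CASE1_c003
CASE1_c004
CASE1_c005
CASE1_c006
CASE1_c007
CASE1_c008
CASE1_c009
CASE1_c010
CASE1_c011
CASE1_c012
CASE1_c013
CASE1_c014
CASE1_c015
CASE2_c001
CASE2_c002
CASE2_c003
CASE2_c004
CASE2_c005
CASE2_c006
CASE2_c007
CASE2_c008
CASE2_c009
CASE2_c010
CASE2_c011
CASE2_c012
CASE2_c013
CASE2_c014
CASE2_c015
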