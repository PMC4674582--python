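protein,pdb_id,dG_exp,dG_bind,dE,dG_v,dG_t,dG_r,dG_all
CHK1,4FT0,-10.1,82.2,63.8,-3.9,10.6,10.3,1.4
CHK1,4FT9,-10.9,-48.5,-63.7,-5.0,10.4,9.9,-0.1
CHK1,4FSW,-6.8,-44.2,-60.2,-3.7,10.3,9.4,0.0
CHK1,4FTA,-9.8,-9.8,-30.4,-0.2,10.6,10.1,0.1
ERK2,4FV5,-10.9,-79.3,-102.1,0.5,10.7,10.6,1.0
ERK2,4FV6,-12.3,-74.6,-96.8,-0.4,10.8,10.7,1.1
Thrombin,1DWC,-10.5,-128.5,-144.9,-4.2,10.9,10.5,0.2
Thrombin,1TOM,-11.8,-224.1,-248.7,2.7,10.7,10.5,0.7
Urokinase,1C5Y,-6.0,-16.3,-34.8,-0.7,10.0,8.7,0.5
Urokinase,1F5L,-7.5,34.7,17.4,-2.3,10.2,9.3,0.1
Urokinase,1O3P,-9.4,23.8,3.9,-2.0,10.6,10.2,1.1
Urokinase,1SQO,-10.6,-4.6,-24.8,-0.4,10.3,9.6,0.7
Urokinase,1VJ9,-10.7,-25.9,-50.7,2.4,11.0,10.8,0.6
Urokinase,1VJA,-10.9,-31.0,-51.1,-2.1,10.9,10.5,0.8
FactorXa,2P94,-13.0,-42.0,-68.2,-5.5,10.9,10.8,0.0
FactorXa,3CEN,-11.7,-49.2,-69.5,-1.9,10.9,10.6,0.7
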