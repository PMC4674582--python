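pdb_id,dG_exp,{1}MMFF94,{1}MMFF94+PCM,{1}PM7,{1}PM7+COSMO,{2}MMFF94,{2}MMFF94+PCM,{2}MMFF94+SGB,SOL,Autodock
4FT0,-10.1,63.84,0.04,-39.48,-48.67,58.64,-0.08,3.03,-5.20,-7.15
4FT9,-10.9,-63.72,-9.98,-111.64,-48.77,-64.83,-10.05,-16.34,-4.29,-4.9
4FSW,-6.8,-60.20,-5.89,-108.48,-46.41,-60.19,-6.53,-7.72,-4.78,-6.08
4FTA,-9.8,-30.36,-5.44,-126.54,-58.61,-30.35,-15.04,-14.05,-4.35,-4.7
4FV5,-10.9,-102.01,-7.42,-168.44,-54.37,-102.01,-4.64,-11.16,-6.05,-8.25
4FV6,-12.3,-96.92,-7.75,-164.91,-72.68,-89.27,-13.42,-13.87,-5.26,-5.6
1DWC,-10.5,-146.16,-33.43,-194.69,-70.12,-144.88,-32.93,-36.77,-2.86,-4.24
1TOM,-11.8,-248.29,-49.66,-258.10,-73.67,-248.28,-49.89,-51.59,-8.11,-7.88
1C5Y,-6.0,-34.83,-79.15,-33.81,-52.84,-34.83,-79.34,-80.85,-6.83,-5.28
1F5L,-7.5,17.40,-52.26,-29.98,-81.95,17.40,-52.54,-52.88,-4.41,-6.62
1O3P,-9.4,3.59,-40.30,-32.53,-64.60,3.59,-40.59,-42.54,-6.95,-8.43
1SQO,-10.6,-24.78,-50.42,-58.75,-69.56,-24.78,-51.30,-52.22,-6.75,-8.68
1VJ9,-10.7,-49.57,-50.03,-91.69,-76.58,-49.20,-43.77,-49.18,-4.53,-3.17
1VJA,-10.9,-49.87,-51.91,-95.43,-81.40,-47.97,-38.86,-41.85,-4.47,-1.82
2P94,-13.0,-68.20,-15.74,-153.53,-68.94,-67.28,-15.79,-20.87,-6.53,-13.09
3CEN,-11.7,-69.48,-18.17,-133.10,-63.12,-69.47,-18.43,-26.62,-5.48,-11.68
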