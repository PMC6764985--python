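id,sex,max_displacement_km,total_distance_km,n_locations,pct_resident
112724,male,4969,5298,451,63
112744,unknown,2491,3551,42,9
113215,male,5574,10300,2019,79
113218,male,3743,4692,134,0
113220,female,5401,11474,669,66
131140,female,4249,4284,205,70
154848,male,4430,5752,79,1
154852,unknown,4566,7854,305,34
154859,female,4020,8493,225,47
154867,unknown,4667,8610,798,85
154875,female,4410,6075,134,61
154876,unknown,3598,3777,53,44
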