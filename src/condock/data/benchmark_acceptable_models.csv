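pdb_id,docking,retained,constrained,unconstrained,correct_constraint
1gla,unbound,500,0,0,False
1gla,unbound,1000,0,0,False
1gla,unbound,2000,0,0,False
1gla,unbound,5000,0,0,False
1gla,bound,500,1,1,False
1gla,bound,1000,2,2,False
1gla,bound,2000,2,4,False
1gla,bound,5000,7,8,False
1y64,unbound,500,0,0,False
1y64,unbound,1000,0,0,False
1y64,unbound,2000,0,0,False
1y64,unbound,5000,0,0,False
1y64,bound,500,0,1,False
1y64,bound,1000,0,2,False
1y64,bound,2000,0,2,False
1y64,bound,5000,0,3,False
1akj,unbound,500,10,3,False
1akj,unbound,1000,13,5,False
1akj,unbound,2000,15,6,False
1akj,unbound,5000,26,13,False
1akj,bound,500,5,5,False
1akj,bound,1000,8,8,False
1akj,bound,2000,14,12,False
1akj,bound,5000,18,21,False
1s1q,unbound,500,0,0,False
1s1q,unbound,1000,0,0,False
1s1q,unbound,2000,0,0,False
1s1q,unbound,5000,0,0,False
1s1q,bound,500,4,12,False
1s1q,bound,1000,5,16,False
1s1q,bound,2000,6,30,False
1s1q,bound,5000,8,41,False
3bp8,unbound,500,4,0,False
3bp8,unbound,1000,5,2,False
3bp8,unbound,2000,9,4,False
3bp8,unbound,5000,27,14,False
3bp8,bound,500,9,8,False
3bp8,bound,1000,10,13,False
3bp8,bound,2000,12,25,False
3bp8,bound,5000,18,42,False
1pvh,unbound,500,0,0,True
1pvh,unbound,1000,0,0,True
1pvh,unbound,2000,0,0,True
1pvh,unbound,5000,0,0,True
1pvh,bound,500,2,1,True
1pvh,bound,1000,2,1,True
1pvh,bound,2000,3,2,True
1pvh,bound,5000,5,3,True
2nz8,unbound,500,1,1,True
2nz8,unbound,1000,1,1,True
2nz8,unbound,2000,3,2,True
2nz8,unbound,5000,4,3,True
2nz8,bound,500,23,9,True
2nz8,bound,1000,38,10,True
2nz8,bound,2000,50,12,True
2nz8,bound,5000,70,23,True
2j0t,unbound,500,2,2,True
2j0t,unbound,1000,3,2,True
2j0t,unbound,2000,7,3,True
2j0t,unbound,5000,11,7,True
2j0t,bound,500,10,5,True
2j0t,bound,1000,12,5,True
2j0t,bound,2000,20,8,True
2j0t,bound,5000,30,20,True
7cei,unbound,500,0,1,True
7cei,unbound,1000,0,1,True
7cei,unbound,2000,0,1,True
7cei,unbound,5000,0,4,True
7cei,bound,500,5,1,True
7cei,bound,1000,6,1,True
7cei,bound,2000,7,1,True
7cei,bound,5000,7,1,True
1ijk,unbound,500,0,0,True
1ijk,unbound,1000,0,0,True
1ijk,unbound,2000,0,0,True
1ijk,unbound,5000,1,1,True
1ijk,bound,500,2,2,True
1ijk,bound,1000,2,2,True
1ijk,bound,2000,3,3,True
1ijk,bound,5000,5,5,True
2o3b,unbound,500,0,0,True
2o3b,unbound,1000,0,0,True
2o3b,unbound,2000,0,0,True
2o3b,unbound,5000,10,4,True
2o3b,bound,500,0,0,True
2o3b,bound,1000,0,0,True
2o3b,bound,2000,0,0,True
2o3b,bound,5000,1,1,True
1jwh,unbound,500,0,0,True
1jwh,unbound,1000,1,0,True
1jwh,unbound,2000,5,0,True
1jwh,unbound,5000,9,1,True
1jwh,bound,500,0,0,True
1jwh,bound,1000,0,0,True
1jwh,bound,2000,0,0,True
1jwh,bound,5000,3,0,True
1i2m,unbound,500,0,0,True
1i2m,unbound,1000,0,0,True
1i2m,unbound,2000,0,0,True
1i2m,unbound,5000,3,0,True
1i2m,bound,500,1,1,True
1i2m,bound,1000,3,1,True
1i2m,bound,2000,6,3,True
1i2m,bound,5000,12,6,True
2pcc,unbound,500,2,0,True
2pcc,unbound,1000,3,0,True
2pcc,unbound,2000,4,1,True
2pcc,unbound,5000,8,1,True
2pcc,bound,500,2,0,True
2pcc,bound,1000,5,5,True
2pcc,bound,2000,8,6,True
2pcc,bound,5000,15,13,True
1h1v,unbound,500,0,0,True
1h1v,unbound,1000,0,0,True
1h1v,unbound,2000,0,0,True
1h1v,unbound,5000,0,0,True
1h1v,bound,500,2,2,True
1h1v,bound,1000,3,3,True
1h1v,bound,2000,5,6,True
1h1v,bound,5000,10,8,True
1b6c,unbound,500,0,0,True
1b6c,unbound,1000,1,1,True
1b6c,unbound,2000,2,1,True
1b6c,unbound,5000,2,1,True
1b6c,bound,500,21,25,True
1b6c,bound,1000,36,35,True
1b6c,bound,2000,62,43,True
1b6c,bound,5000,117,61,True
2hle,unbound,500,1,0,True
2hle,unbound,1000,2,1,True
2hle,unbound,2000,3,1,True
2hle,unbound,5000,11,3,True
2hle,bound,500,2,0,True
2hle,bound,1000,4,0,True
2hle,bound,2000,9,2,True
2hle,bound,5000,16,5,True
1bkd,unbound,500,0,0,True
1bkd,unbound,1000,0,0,True
1bkd,unbound,2000,0,0,True
1bkd,unbound,5000,0,0,True
1bkd,bound,500,19,6,True
1bkd,bound,1000,35,9,True
1bkd,bound,2000,67,15,True
1bkd,bound,5000,106,20,True
1he1,unbound,500,11,6,True
1he1,unbound,1000,18,12,True
1he1,unbound,2000,30,17,True
1he1,unbound,5000,53,34,True
1he1,bound,500,32,3,True
1he1,bound,1000,42,5,True
1he1,bound,2000,77,9,True
1he1,bound,5000,140,17,True
1m10,unbound,500,16,5,True
1m10,unbound,1000,19,5,True
1m10,unbound,2000,27,11,True
1m10,unbound,5000,54,17,True
1m10,bound,500,36,9,True
1m10,bound,1000,54,14,True
1m10,bound,2000,75,17,True
1m10,bound,5000,106,22,True
1i4d,unbound,500,0,0,True
1i4d,unbound,1000,0,0,True
1i4d,unbound,2000,0,0,True
1i4d,unbound,5000,0,0,True
1i4d,bound,500,4,7,True
1i4d,bound,1000,5,8,True
1i4d,bound,2000,9,11,True
1i4d,bound,5000,13,22,True
1azs,unbound,500,0,0,True
1azs,unbound,1000,0,0,True
1azs,unbound,2000,0,0,True
1azs,unbound,5000,0,0,True
1azs,bound,500,16,2,True
1azs,bound,1000,24,2,True
1azs,bound,2000,48,3,True
1azs,bound,5000,58,7,True
2sni,unbound,500,1,1,True
2sni,unbound,1000,1,2,True
2sni,unbound,2000,1,3,True
2sni,unbound,5000,3,16,True
2sni,bound,500,26,14,True
2sni,bound,1000,41,26,True
2sni,bound,2000,70,38,True
2sni,bound,5000,142,82,True
1gpw,unbound,500,0,1,True
1gpw,unbound,1000,2,1,True
1gpw,unbound,2000,2,3,True
1gpw,unbound,5000,13,10,True
1gpw,bound,500,25,14,True
1gpw,bound,1000,42,22,True
1gpw,bound,2000,73,26,True
1gpw,bound,5000,132,41,True
1ofu,unbound,500,3,0,True
1ofu,unbound,1000,4,0,True
1ofu,unbound,2000,6,1,True
1ofu,unbound,5000,10,1,True
1ofu,bound,500,7,0,True
1ofu,bound,1000,18,0,True
1ofu,bound,2000,38,2,True
1ofu,bound,5000,75,4,True
1z0k,unbound,500,1,1,True
1z0k,unbound,1000,3,1,True
1z0k,unbound,2000,16,4,True
1z0k,unbound,5000,39,20,True
1z0k,bound,500,36,17,True
1z0k,bound,1000,58,27,True
1z0k,bound,2000,92,43,True
1z0k,bound,5000,179,85,True
1jzd,unbound,500,0,0,True
1jzd,unbound,1000,0,0,True
1jzd,unbound,2000,1,0,True
1jzd,unbound,5000,2,4,True
1jzd,bound,500,29,7,True
1jzd,bound,1000,44,13,True
1jzd,bound,2000,67,14,True
1jzd,bound,5000,110,27,True
1fak,unbound,500,0,0,True
1fak,unbound,1000,0,0,True
1fak,unbound,2000,0,0,True
1fak,unbound,5000,1,0,True
1fak,bound,500,0,1,True
1fak,bound,1000,1,2,True
1fak,bound,2000,6,4,True
1fak,bound,5000,11,6,True
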